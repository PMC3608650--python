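"""Quality control of crowdsourced image ratings and exemplar-set selection.

Raters see a self-consistency "check" trial after every ten regular trials:
the check repeats one of the rater's preceding ten images.  A per-rater
discount score accumulates 5 for a changed category response and the absolute
rating difference otherwise; raters whose total exceeds 10 are discarded.
Images judged a non-member of their category ("none" or another category) on
more than a quarter of their ratings are discarded.  Finally, 240 ranked
candidates per category (80 good / 80 medium / 80 bad) are reduced to three
mutually exclusive sets of 60 exemplars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DISCOUNT_CATEGORY_FLIP = 5
RATER_DISCOUNT_THRESHOLD = 10
IMAGE_NONMEMBER_FRACTION = 0.25


@dataclass
class DiscountLedger:
    """Per-rater discount totals with the per-check-trial contributions."""

    totals: pd.Series  # index rater_id -> total discount
    contributions: pd.DataFrame  # columns: rater_id, trial, refers_to, contribution

    def total(self, rater_id: str) -> int:
        return int(self.totals.get(rater_id, 0))


def discount_score(ratings: pd.DataFrame) -> DiscountLedger:
    """Score every check trial against the trial it repeats.

    A check contributes 5 when its category response differs from the original
    response, otherwise the absolute difference between the two 1-5 ratings.
    A check whose ``refers_to`` does not resolve to a trial by the same rater
    is an error.
    """
    required = {"rater_id", "trial", "response", "rating", "is_check", "refers_to"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"rating table lacks columns: {sorted(missing)}")
    rows = []
    totals: dict[str, int] = {}
    for rater_id, group in ratings.groupby("rater_id", sort=True):
        by_trial = group.set_index("trial")
        totals.setdefault(str(rater_id), 0)
        for _, check in group[group["is_check"].astype(bool)].iterrows():
            ref = check["refers_to"]
            if pd.isna(ref):
                raise ValueError(f"check trial {check['trial']} of {rater_id} has no reference")
            ref = int(ref)
            if ref not in by_trial.index or ref >= int(check["trial"]):
                raise ValueError(
                    f"check trial {check['trial']} of {rater_id} references missing/later trial {ref}"
                )
            original = by_trial.loc[ref]
            if str(check["response"]) != str(original["response"]):
                contribution = DISCOUNT_CATEGORY_FLIP
            else:
                contribution = int(abs(int(check["rating"]) - int(original["rating"])))
            totals[str(rater_id)] += contribution
            rows.append((str(rater_id), int(check["trial"]), ref, contribution))
    contributions = pd.DataFrame(rows, columns=["rater_id", "trial", "refers_to", "contribution"])
    return DiscountLedger(pd.Series(totals, dtype=int).sort_index(), contributions)


def filter_raters(ledger: DiscountLedger, threshold: int = RATER_DISCOUNT_THRESHOLD) -> list[str]:
    """Rater ids whose total discount does not exceed the threshold (strict >)."""
    return sorted(ledger.totals.index[ledger.totals <= threshold])


def filter_images(
    image_responses: pd.DataFrame, fraction: float = IMAGE_NONMEMBER_FRACTION
) -> list:
    """Image ids retained after the non-member-response rule.

    ``image_responses`` needs columns ``image_id`` and ``is_member`` (False for
    a "none of them" or other-category response).  An image is excluded when
    its non-member responses strictly exceed ``fraction`` of its ratings.
    """
    required = {"image_id", "is_member"}
    missing = required - set(image_responses.columns)
    if missing:
        raise ValueError(f"image response table lacks columns: {sorted(missing)}")
    grouped = image_responses.groupby("image_id")["is_member"]
    total = grouped.count()
    if (total == 0).any():
        raise ValueError("every image needs at least one rating")
    nonmember = grouped.apply(lambda s: int((~s.astype(bool)).sum()))
    keep = nonmember <= fraction * total
    return sorted(total.index[keep])


@dataclass
class ExemplarSets:
    """The three mutually exclusive 60-image exemplar sets."""

    good: list
    medium: list
    bad: list

    def __post_init__(self) -> None:
        sets = [set(self.good), set(self.medium), set(self.bad)]
        if any(len(s) != 60 for s in sets):
            raise ValueError("each exemplar set must contain exactly 60 images")
        if len(sets[0] | sets[1] | sets[2]) != 180:
            raise ValueError("exemplar sets must be mutually exclusive")


def select_exemplar_sets(candidates: pd.DataFrame, set_size: int = 60) -> ExemplarSets:
    """Reduce 240 ranked candidates to good/medium/bad sets of 60.

    ``candidates`` needs columns ``image_id``, ``mean_rating`` and
    ``candidate_class`` (80 each of "good", "medium", "bad").  The good set is
    the 60 highest-rated good candidates; the bad set the 60 lowest-rated bad
    candidates; the medium set the 60 central images of the full descending
    ranking (ranks 91-150 of 240).  Ties in mean rating break by image id so
    the ranking is deterministic.
    """
    required = {"image_id", "mean_rating", "candidate_class"}
    missing = required - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table lacks columns: {sorted(missing)}")
    df = candidates.copy()
    if df["image_id"].duplicated().any():
        raise ValueError("duplicate image ids in candidate table")
    counts = df["candidate_class"].value_counts()
    for cls in ("good", "medium", "bad"):
        if counts.get(cls, 0) != 80:
            raise ValueError(f"expected 80 {cls!r} candidates, got {counts.get(cls, 0)}")
    ranked = df.sort_values(["mean_rating", "image_id"], ascending=[False, True]).reset_index(drop=True)

    good_cands = ranked[ranked["candidate_class"] == "good"]
    bad_cands = ranked[ranked["candidate_class"] == "bad"]
    good = good_cands.head(set_size)["image_id"].tolist()
    bad = bad_cands.tail(set_size)["image_id"].tolist()
    mid_start = (len(ranked) - set_size) // 2  # ranks 91..150 of 240 (0-based 90..149)
    medium = ranked.iloc[mid_start : mid_start + set_size]["image_id"].tolist()
    overlap = (set(good) & set(medium)) | (set(good) & set(bad)) | (set(medium) & set(bad))
    if overlap:
        raise ValueError(f"selection rule produced overlapping sets (e.g. {sorted(overlap)[:5]})")
    return ExemplarSets(good=good, medium=medium, bad=bad)


def mean_ratings(ratings: pd.DataFrame, retained_raters: list[str] | None = None,
                 include_checks: bool = False) -> pd.Series:
    """Mean 1-5 rating per image over retained raters (check trials excluded by default)."""
    df = ratings
    if retained_raters is not None:
        df = df[df["rater_id"].isin(retained_raters)]
    if not include_checks:
        df = df[~df["is_check"].astype(bool)]
    return df.groupby("image_id")["rating"].mean()
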