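"""QC filtering and the stratified three-way cohort split.

The split first stratifies on genotype availability, then partitions
each stratum into thirds. When a stratum size n is not divisible by 3,
the remainder goes to train first and validation second: sizes are
floor(n/3)+1 if r>=1, floor(n/3)+1 if r>=2, floor(n/3), where r = n mod 3.
This is the only rounding convention consistent with subset totals of
3,062/3,062/3,060 arising from strata of 4,544 and 4,640.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import stream

__all__ = [
    "QC_FLAG_COLUMNS",
    "FilterReport",
    "SplitAssignment",
    "filter_cohort",
    "split_thirds",
    "thirds_sizes",
]

QC_FLAG_COLUMNS = ["qc_outlier", "qc_related", "qc_race_mismatch"]
SUBSETS = ["train", "validation", "test"]


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    removed_by_reason: dict[str, int]
    n_removed: int
    overlap_note: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": k, "n": v} for k, v in self.removed_by_reason.items()]
        rows.append({"reason": "any_flag", "n": self.n_removed})
        return pd.DataFrame(rows)


def filter_cohort(participants: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop rows carrying any QC flag (outlier / related / race mismatch).

    Returns the retained table and a report counting removals per
    reason; reasons may overlap, so per-reason counts can sum to more
    than the number removed.
    """
    missing = [c for c in QC_FLAG_COLUMNS if c not in participants.columns]
    if missing:
        raise ValueError(f"participant table lacks QC flag columns: {missing}")
    flags = participants[QC_FLAG_COLUMNS].astype(bool)
    any_flag = flags.any(axis=1)
    retained = participants.loc[~any_flag].reset_index(drop=True)
    per_reason = {c: int(flags[c].sum()) for c in QC_FLAG_COLUMNS}
    n_multi = int((flags.sum(axis=1) > 1).sum())
    report = FilterReport(
        n_input=len(participants),
        n_retained=len(retained),
        removed_by_reason=per_reason,
        n_removed=int(any_flag.sum()),
        overlap_note=f"{n_multi} rows carried more than one flag",
    )
    return retained, report


def thirds_sizes(n: int) -> tuple[int, int, int]:
    """Subset sizes for a stratum of size n (remainder to train, then
    validation)."""
    base, r = divmod(n, 3)
    return base + (1 if r >= 1 else 0), base + (1 if r >= 2 else 0), base


@dataclass
class SplitAssignment:
    assignment: pd.Series  # id -> subset label
    seed: int
    stratum_counts: pd.DataFrame = field(repr=False)

    def ids(self, subset: str) -> list[str]:
        return self.assignment.index[self.assignment == subset].tolist()

    def counts(self) -> dict[str, int]:
        return {s: int((self.assignment == s).sum()) for s in SUBSETS}

    def to_frame(self, participants: pd.DataFrame | None = None) -> pd.DataFrame:
        frame = self.assignment.rename("subset").rename_axis("id").reset_index()
        if participants is not None:
            wgs = participants.set_index("id")["wgs_available"]
            frame["wgs_available"] = wgs.loc[frame["id"]].to_numpy()
        return frame

    def to_tsv(self, path: str | Path, participants: pd.DataFrame | None = None) -> None:
        self.to_frame(participants).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SplitAssignment":
        frame = pd.read_csv(path, sep="\t")
        assignment = pd.Series(
            frame["subset"].to_numpy(), index=pd.Index(frame["id"], name="id")
        )
        return cls(assignment=assignment, seed=-1, stratum_counts=pd.DataFrame())


def split_thirds(participants: pd.DataFrame, seed: int) -> SplitAssignment:
    """Random thirds split within each genotype-availability stratum.

    Sizes are a deterministic function of stratum sizes; only the
    membership depends on the seed.
    """
    if "wgs_available" not in participants.columns:
        raise ValueError("participant table lacks 'wgs_available' column")
    rng = stream(seed, "split_thirds")
    labels = pd.Series(index=participants["id"], dtype=object)
    records = []
    # iterate strata in a fixed order so seeding is stable
    for wgs_value in (True, False):
        ids = participants.loc[
            participants["wgs_available"].astype(bool) == wgs_value, "id"
        ].to_numpy()
        n = len(ids)
        n_train, n_val, n_test = thirds_sizes(n)
        perm = rng.permutation(n)
        shuffled = ids[perm]
        labels.loc[shuffled[:n_train]] = "train"
        labels.loc[shuffled[n_train : n_train + n_val]] = "validation"
        labels.loc[shuffled[n_train + n_val :]] = "test"
        records.append(
            {
                "wgs_available": wgs_value,
                "n": n,
                "train": n_train,
                "validation": n_val,
                "test": n_test,
            }
        )
    return SplitAssignment(
        assignment=labels, seed=seed, stratum_counts=pd.DataFrame(records)
    )
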