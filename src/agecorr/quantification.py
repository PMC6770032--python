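"""Relative quantification of qPCR data by the 2^-ddCt method.

Each well pairs a target assay Ct with a housekeeping reference Ct
(dCt = Ct_target - Ct_reference); the relative quantity of a sample against a
calibrator is 2^-(dCt_sample - dCt_calibrator).  Group summaries calibrate to
the mean dCt of the reference group, which is the geometric-mean convention
standard for this method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CtRecord",
    "ddct_fold_change",
    "group_fold_change",
    "read_ct_table",
    "fold_change_table",
]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: target and housekeeping Ct for a sample/assay."""

    sample_id: str
    assay_id: str
    ct_target: float
    ct_reference: float
    group: str = ""

    def __post_init__(self):
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(
                    f"{name} must be positive and finite, got {v} "
                    f"(sample {self.sample_id!r}, assay {self.assay_id!r})"
                )

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold_change(sample: CtRecord, calibrator: CtRecord) -> float:
    """2^-ddCt fold change of ``sample`` relative to ``calibrator``.

    Both records must measure the same assay.  ddCt = dCt_sample -
    dCt_calibrator; one cycle of dCt difference is a two-fold change.
    """
    if sample.assay_id != calibrator.assay_id:
        raise ValueError(
            f"assay mismatch: {sample.assay_id!r} vs {calibrator.assay_id!r}"
        )
    return 2.0 ** -(sample.delta_ct - calibrator.delta_ct)


def group_fold_change(records, group_a: str, group_b: str) -> dict:
    """Per-assay fold change of group_a relative to group_b.

    Computed as 2^-(mean dCt_a - mean dCt_b), i.e. each group's geometric-mean
    quantity calibrated to group_b.  Assays present in only one group are
    skipped with a warning; an assay in neither group is an error.
    """
    by_assay: dict[str, dict[str, list]] = {}
    for r in records:
        by_assay.setdefault(r.assay_id, {}).setdefault(r.group, []).append(r.delta_ct)
    if not by_assay:
        raise ValueError("no Ct records supplied")
    folds = {}
    for assay, groups in sorted(by_assay.items()):
        a, b = groups.get(group_a), groups.get(group_b)
        if not a or not b:
            warnings.warn(
                f"assay {assay!r} missing group {group_a if not a else group_b!r}; skipped"
            )
            continue
        mean_a = sum(a) / len(a)
        mean_b = sum(b) / len(b)
        folds[assay] = 2.0 ** -(mean_a - mean_b)
    return folds


def read_ct_table(path) -> list:
    """Read a tidy Ct CSV: sample_id, assay_id, ct_target, ct_reference, group."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = ("sample_id", "assay_id", "ct_target", "ct_reference", "group")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) in {path}: {', '.join(missing)}")
    return [
        CtRecord(
            sample_id=str(row.sample_id),
            assay_id=str(row.assay_id),
            ct_target=float(row.ct_target),
            ct_reference=float(row.ct_reference),
            group=str(row.group),
        )
        for row in df.itertuples(index=False)
    ]


def fold_change_table(records, group_a: str, group_b: str) -> pd.DataFrame:
    folds = group_fold_change(records, group_a, group_b)
    return pd.DataFrame(
        {"assay_id": list(folds), f"fold_{group_a}_vs_{group_b}": list(folds.values())}
    )
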