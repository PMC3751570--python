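"""Evaluation of automated progression calls against a reader panel.

The reference standard is the majority vote of three independent readers on
the two-or-more-new-lesions progression criterion; patients any reader panel
flags as undecidable are excluded from the evaluable set.  Standard 2x2
diagnostic metrics (sensitivity, specificity, PPV, NPV) are reported as
integer percentages (round half up, matching conventional clinical
reporting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


class CohortError(ValueError):
    pass


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ReaderPanel:
    """Per-patient reader calls with the majority-rule consensus."""

    reads: dict[str, tuple[bool, ...] | None]   # patient -> 3 calls, None = undecidable
    consensus_calls: dict[str, bool]            # evaluable patients only

    @property
    def evaluable(self) -> tuple[str, ...]:
        return tuple(sorted(self.consensus_calls))

    @property
    def excluded(self) -> tuple[str, ...]:
        return tuple(sorted(p for p, r in self.reads.items() if r is None))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise CohortError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def consensus(reads: dict[str, tuple[bool, ...] | None]) -> ReaderPanel:
    """Majority-rule consensus of three reads per patient.

    ``None`` marks a patient the panel could not decide; such patients are
    excluded from the evaluable set.
    """
    calls: dict[str, bool] = {}
    for patient, r in reads.items():
        if r is None:
            continue
        if len(r) != 3:
            raise CohortError(f"patient {patient}: need 3 reads or an undecidable flag")
        calls[patient] = sum(bool(v) for v in r) >= 2
    return ReaderPanel(reads=dict(reads), consensus_calls=calls)


def confusion(auto_calls: dict[str, bool], panel: ReaderPanel) -> ConfusionCounts:
    """2x2 cross-tabulation of automated calls against the panel consensus."""
    evaluable = set(panel.consensus_calls)
    if not evaluable:
        raise CohortError("empty evaluable set")
    if set(auto_calls) < evaluable:
        missing = sorted(evaluable - set(auto_calls))
        raise CohortError(f"automated calls missing for patients: {missing}")
    tp = fp = tn = fn = 0
    for patient in evaluable:
        ref = panel.consensus_calls[patient]
        auto = bool(auto_calls[patient])
        if ref and auto:
            tp += 1
        elif ref and not auto:
            fn += 1
        elif not ref and auto:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> dict[str, int | None]:
    """Sensitivity, specificity, PPV and NPV as integer percentages.

    A metric whose denominator is zero is reported as ``None``.
    """
    def pct(num: int, den: int) -> int | None:
        return round_half_up(100.0 * num / den) if den > 0 else None

    return {
        "sensitivity": pct(c.tp, c.tp + c.fn),
        "specificity": pct(c.tn, c.tn + c.fp),
        "ppv": pct(c.tp, c.tp + c.fp),
        "npv": pct(c.tn, c.tn + c.fn),
    }


def agreement_rate(reads: dict[str, tuple[bool, ...] | None]) -> int:
    """Percentage of evaluable patients on whom all readers agree."""
    panel = consensus(reads)
    evaluable = panel.evaluable
    if not evaluable:
        raise CohortError("empty evaluable set")
    unanimous = sum(1 for p in evaluable if len(set(reads[p])) == 1)
    return round_half_up(100.0 * unanimous / len(evaluable))


# ---------------------------------------------------------------------------
# CSV ingest: patient_id, reader_id, call, undecidable
# ---------------------------------------------------------------------------

def read_panel_csv(path) -> dict[str, tuple[bool, ...] | None]:
    df = pd.read_csv(path)
    required = {"patient_id", "reader_id", "call", "undecidable"}
    if not required <= set(df.columns):
        raise CohortError(f"reads file must have columns {sorted(required)}")
    reads: dict[str, tuple[bool, ...] | None] = {}
    for patient, sub in df.groupby("patient_id", sort=True):
        if sub["undecidable"].astype(bool).any():
            reads[str(patient)] = None
        else:
            sub = sub.sort_values("reader_id")
            reads[str(patient)] = tuple(bool(v) for v in sub["call"])
    return reads


def simulate_reader_panel(truth_progression: dict[str, bool], flip_probability: float,
                          seed: int, n_readers: int = 3) -> dict[str, tuple[bool, ...] | None]:
    """Synthetic reader panel: truth with independent per-reader flips."""
    import numpy as np

    rng = np.random.default_rng(seed)
    return {
        patient: tuple(bool(truth ^ (rng.random() < flip_probability))
                       for _ in range(n_readers))
        for patient, truth in sorted(truth_progression.items())
    }
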