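"""Convenience wrappers chaining the per-subject processing steps."""

from __future__ import annotations

import numpy as np

from .fc import RegionalTimeSeries, regress_nuisance, wavelet_fc
from .sc import reconcile_runs

__all__ = ["subject_connectomes", "cohort_connectomes"]


def subject_connectomes(subject):
    """(reconciled SC, wavelet FC) for one synthetic subject."""
    rec = reconcile_runs(subject.run1, subject.run2)
    ts = regress_nuisance(RegionalTimeSeries(subject.bold, subject.tr, subject.confounds))
    return rec.weights, wavelet_fc(ts)


def cohort_connectomes(cohort: dict) -> dict:
    """Per-group lists of (SC, FC) matrices for a generated cohort."""
    out = {}
    for group in ("controls", "patients"):
        sc, fc = [], []
        for subj in cohort[group]:
            w, f = subject_connectomes(subj)
            sc.append(w)
            fc.append(f)
        out[group] = {"sc": sc, "fc": fc}
    return out
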