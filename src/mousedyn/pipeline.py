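"""End-to-end study pipeline.

Reproduces the full analysis flow on two participant samples: uniform
resampling and joint length-trimming, per-participant spectra, a
reference subspace fit on sample 1's high-accuracy group, η projection
of every sample-2 participant, a Welch t-test contrasting η between
sample 2's high and low accuracy groups, OLS linking η and accuracy
(both regression directions are reported), per-participant DFA
exponents, and OLS linking α and accuracy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import dfa as _dfa
from .preprocess import RawTrace, resample_uniform, trim_cohort
from .spectral import dft
from .subspace import ReferenceSubspace, eta, fit_reference_subspace

__all__ = ["GroupSplit", "StudyReport", "split_groups", "welch_ttest",
           "ols_fit", "run_study"]


@dataclass
class GroupSplit:
    """High/low performance ids; boundary accuracies are excluded (strict)."""

    high_ids: list[str]
    low_ids: list[str]
    hi_threshold: float = 0.505
    lo_threshold: float = 0.12


@dataclass
class StudyReport:
    """All study-level statistics plus per-participant η and α tables."""

    k: int
    variance_fraction: float
    eta_by_id: dict[str, float]
    alpha_by_id: dict[str, float]
    accuracy_by_id: dict[str, float]
    split_sample1: GroupSplit
    split_sample2: GroupSplit
    welch_eta: dict = field(default_factory=dict)
    ols_eta_on_accuracy: dict = field(default_factory=dict)
    ols_accuracy_on_eta: dict = field(default_factory=dict)
    ols_alpha_on_accuracy: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def split_groups(accuracy: dict[str, float], hi: float = 0.505,
                 lo: float = 0.12) -> GroupSplit:
    """Partition participants into strict high (> hi) and low (< lo) groups."""
    if not 0 <= lo < hi <= 1:
        raise ValueError("need 0 <= lo < hi <= 1")
    high = [pid for pid, a in accuracy.items() if a > hi]
    low = [pid for pid, a in accuracy.items() if a < lo]
    if not high or not low:
        warnings.warn("empty high or low performance group")
    return GroupSplit(high_ids=high, low_ids=low, hi_threshold=hi,
                      lo_threshold=lo)


def welch_ttest(x, y) -> dict:
    """Unequal-variance two-sample t-test with Welch–Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 samples per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.allclose(x.mean(), y.mean()):
            return {"t": 0.0, "p": 1.0, "df": float(len(x) + len(y) - 2)}
        raise ValueError("both groups degenerate (zero variance)")
    res = stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "df": float(res.df)}


def ols_fit(x, y) -> dict:
    """Simple OLS of ``y`` on ``x`` with conventional slope standard error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("predictor has zero variance")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "se_slope": float(res.stderr), "r2": float(res.rvalue ** 2),
            "p": float(res.pvalue), "n": int(len(x))}


def run_study(sample1: list[RawTrace], sample2: list[RawTrace],
              dt: float = 20.0, variance_threshold: float = 0.5,
              hi: float = 0.505, lo: float = 0.12,
              dfa_kwargs: dict | None = None,
              subspace: ReferenceSubspace | None = None) -> StudyReport:
    """Run the whole study on two raw-trace samples carrying accuracies.

    Steps: (1) resample both samples to ``dt`` and trim jointly to the
    shortest trace across their union; (2) compute spectra; (3) fit the
    reference subspace on sample 1's high-accuracy group at
    ``variance_threshold`` (unless a pre-fit ``subspace`` is supplied);
    (4) project every sample-2 spectrum to get η; (5) Welch t-test of η
    between sample 2's high and low groups; (6) OLS linking accuracy and
    η over all of sample 2, both directions; (7) DFA α per sample-2
    participant; (8) OLS of α on accuracy.
    """
    for stage_check, msg in ((sample1, "sample1"), (sample2, "sample2")):
        if any(tr.accuracy is None for tr in stage_check):
            raise ValueError(f"{msg}: every trace must carry an accuracy")

    uniform_all = [resample_uniform(tr, dt=dt) for tr in sample1 + sample2]
    uniform_all = trim_cohort(uniform_all)
    u1, u2 = uniform_all[: len(sample1)], uniform_all[len(sample1):]

    acc1 = {tr.participant_id: float(tr.accuracy) for tr in u1}
    acc2 = {tr.participant_id: float(tr.accuracy) for tr in u2}
    split1 = split_groups(acc1, hi=hi, lo=lo)
    split2 = split_groups(acc2, hi=hi, lo=lo)

    spec1 = {tr.participant_id: dft(tr) for tr in u1}
    spec2 = {tr.participant_id: dft(tr) for tr in u2}

    flags: list[str] = []
    if subspace is None:
        high_spectra = [spec1[pid] for pid in split1.high_ids]
        if len(high_spectra) < 2:
            raise ValueError("sample 1 high-accuracy group too small to fit "
                             "a reference subspace")
        subspace = fit_reference_subspace(high_spectra,
                                          threshold=variance_threshold)

    eta_by_id = {pid: eta(subspace, sp).eta for pid, sp in spec2.items()}

    welch = {}
    if split2.high_ids and split2.low_ids:
        welch = welch_ttest([eta_by_id[p] for p in split2.high_ids],
                            [eta_by_id[p] for p in split2.low_ids])
    else:
        flags.append("welch_skipped_empty_group")

    ids2 = list(eta_by_id)
    etas = np.array([eta_by_id[p] for p in ids2])
    accs = np.array([acc2[p] for p in ids2])

    def safe_ols(x, y, label):
        try:
            return ols_fit(x, y)
        except ValueError as exc:
            flags.append(f"{label}_degenerate: {exc}")
            return {}

    ols_eta_on_acc = safe_ols(accs, etas, "ols_eta_on_accuracy")
    ols_acc_on_eta = safe_ols(etas, accs, "ols_accuracy_on_eta")

    dfa_kwargs = dfa_kwargs or {}
    alpha_by_id = {}
    for tr in u2:
        try:
            alpha_by_id[tr.participant_id] = _dfa.dfa_alpha(tr.z, **dfa_kwargs).alpha
        except (ValueError, _dfa.DegenerateSeriesError) as exc:
            flags.append(f"dfa_failed:{tr.participant_id}: {exc}")
    alpha_ids = list(alpha_by_id)
    ols_alpha_on_acc = safe_ols(np.array([acc2[p] for p in alpha_ids]),
                                np.array([alpha_by_id[p] for p in alpha_ids]),
                                "ols_alpha_on_accuracy")

    return StudyReport(
        k=subspace.k,
        variance_fraction=subspace.variance_fraction,
        eta_by_id=eta_by_id,
        alpha_by_id=alpha_by_id,
        accuracy_by_id=acc2,
        split_sample1=split1,
        split_sample2=split2,
        welch_eta=welch,
        ols_eta_on_accuracy=ols_eta_on_acc,
        ols_accuracy_on_eta=ols_acc_on_eta,
        ols_alpha_on_accuracy=ols_alpha_on_acc,
        flags=flags,
    )
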