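"""Log-bias-factor statistics for two-pathway agonism comparisons.

Two agonism scales are supported, both on log10:

* ``log_max_ec50`` -- log10(Emax / EC50) from a logistic fit, computed
  as ``log10(Emax%) + pEC50``.  Any multiplicative rescaling of the
  response axis shifts this value by an additive constant that cancels
  in the within-assay differences below.
* ``log_ktau`` -- log10 of the kinetic efficacy kτ (initial response
  rate at a single saturating concentration).

For either scale, per-assay differencing against a reference agonist
gives Δlog (normalised agonism), and differencing Δlog between the two
pathways gives ΔΔlog -- the log bias factor.  The mean ΔΔlog over
assays with its Student-t 95% confidence interval yields the bias call:
a ligand is flagged biased when the interval excludes zero.  Positive
ΔΔlog means bias toward the first-listed pathway.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PathwayAgonism",
    "BiasEstimate",
    "PairedTTest",
    "log_max_ec50",
    "delta_log",
    "delta_log_table",
    "ddelta_log",
    "ktau_bias",
    "bias_from_agonism",
    "paired_compare",
]


@dataclass(frozen=True)
class PathwayAgonism:
    """One per-assay agonism value on a log10 scale."""

    ligand: str
    pathway: str
    assay_id: str
    metric: str  # "log_max_ec50" or "log_ktau"
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("agonism value must be finite")


@dataclass(frozen=True)
class BiasEstimate:
    """Per-assay ΔΔlog values with their summary statistics and bias call.

    ``biased`` is True when the 95% CI excludes zero, False when it
    contains zero, and None when n < 2 leaves the CI undefined.
    """

    test_ligand: str
    reference_ligand: str
    pathway_pair: tuple[str, str]
    metric: str
    per_assay_dd: tuple[float, ...]
    mean: float
    sem: float
    ci95: tuple[float, float] | None
    biased: bool | None
    assay_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return len(self.per_assay_dd)

    def summary(self) -> str:
        ci = ("undefined (n < 2)" if self.ci95 is None
              else f"[{self.ci95[0]:+.3f}, {self.ci95[1]:+.3f}]")
        call = {True: "BIASED", False: "not biased",
                None: "undetermined"}[self.biased]
        toward = self.pathway_pair[0] if self.mean >= 0 else self.pathway_pair[1]
        return "\n".join([
            f"ΔΔ{self.metric}: {self.test_ligand} vs {self.reference_ligand} "
            f"({self.pathway_pair[0]} vs {self.pathway_pair[1]})",
            f"  n assays : {self.n}",
            f"  mean     : {self.mean:+.3f} (toward {toward})",
            f"  SEM      : {self.sem:.3f}" if math.isfinite(self.sem) else
            "  SEM      : undefined",
            f"  95% CI   : {ci}",
            f"  call     : {call}",
        ])

    def to_dict(self) -> dict:
        return {
            "test_ligand": self.test_ligand,
            "reference_ligand": self.reference_ligand,
            "pathway_1": self.pathway_pair[0],
            "pathway_2": self.pathway_pair[1],
            "metric": self.metric,
            "n": self.n,
            "mean": self.mean,
            "sem": self.sem,
            "ci95_lo": None if self.ci95 is None else self.ci95[0],
            "ci95_hi": None if self.ci95 is None else self.ci95[1],
            "biased": self.biased,
            "per_assay_dd": list(self.per_assay_dd),
        }


def log_max_ec50(emax_pct: float, pec50: float) -> float:
    """log10(Emax / EC50) agonism scale, as log10(Emax%) + pEC50.

    With EC50 in molar this equals log10(Emax% / EC50); the units of the
    Emax axis only shift the scale by a constant that cancels in Δlog.
    """
    if emax_pct <= 0:
        raise ValueError("Emax must be positive for the log(max/EC50) scale")
    if not (math.isfinite(pec50) and math.isfinite(emax_pct)):
        raise ValueError("non-finite fit parameters")
    return math.log10(emax_pct) + pec50


def delta_log(test: PathwayAgonism, ref: PathwayAgonism) -> float:
    """Within-assay, within-pathway difference test - reference."""
    if test.pathway != ref.pathway:
        raise ValueError(f"pathway mismatch: {test.pathway} vs {ref.pathway}")
    if test.assay_id != ref.assay_id:
        raise ValueError(f"assay mismatch: {test.assay_id} vs {ref.assay_id}")
    if test.metric != ref.metric:
        raise ValueError(f"metric mismatch: {test.metric} vs {ref.metric}")
    return test.value - ref.value


def delta_log_table(agonism: pd.DataFrame, test: str,
                    reference: str) -> pd.DataFrame:
    """Per-assay Δlog for one test ligand, from a tidy agonism table.

    ``agonism`` needs columns ligand, pathway, assay_id, metric, value;
    pairing is on (pathway, assay_id, metric) and assays missing either
    ligand are dropped.
    """
    required = {"ligand", "pathway", "assay_id", "metric", "value"}
    missing = required - set(agonism.columns)
    if missing:
        raise ValueError(f"agonism table missing columns: {sorted(missing)}")
    keys = ["pathway", "assay_id", "metric"]
    t = agonism[agonism["ligand"] == test].set_index(keys)["value"]
    r = agonism[agonism["ligand"] == reference].set_index(keys)["value"]
    joined = pd.DataFrame({"test": t, "ref": r}).dropna()
    if joined.empty:
        raise ValueError(
            f"no paired assays for {test!r} vs {reference!r}")
    out = joined.reset_index()
    out["dlog"] = out["test"] - out["ref"]
    return out[keys + ["dlog"]]


def _t_ci(values: np.ndarray, level: float = 0.95):
    """Mean, SEM and Student-t CI of a small per-assay sample."""
    n = values.size
    mean = float(np.mean(values))
    if n < 2:
        return mean, float("nan"), None
    sem = float(np.std(values, ddof=1) / math.sqrt(n))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, n - 1))
    return mean, sem, (mean - tcrit * sem, mean + tcrit * sem)


def ddelta_log(dlog_pathway1, dlog_pathway2, *, test_ligand: str = "test",
               reference_ligand: str = "reference",
               pathway_pair: tuple[str, str] = ("pathway1", "pathway2"),
               metric: str = "log_max_ec50",
               assay_ids=None) -> BiasEstimate:
    """ΔΔlog bias factor from paired per-assay Δlog vectors.

    ``dlog_pathway1`` and ``dlog_pathway2`` must be aligned per assay;
    positive ΔΔlog indicates bias toward pathway 1.  With a single assay
    the estimate is returned without a CI and the bias call is None.
    """
    d1 = np.asarray(dlog_pathway1, dtype=float)
    d2 = np.asarray(dlog_pathway2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 1:
        raise ValueError("per-assay Δlog vectors must be 1-D and aligned")
    if d1.size == 0:
        raise ValueError("no paired assays")
    dd = d1 - d2
    mean, sem, ci = _t_ci(dd)
    biased = None if ci is None else not (ci[0] <= 0.0 <= ci[1])
    return BiasEstimate(
        test_ligand=test_ligand, reference_ligand=reference_ligand,
        pathway_pair=pathway_pair, metric=metric,
        per_assay_dd=tuple(float(v) for v in dd),
        mean=mean, sem=sem, ci95=ci, biased=biased,
        assay_ids=tuple(assay_ids) if assay_ids is not None else tuple())


def bias_from_agonism(agonism: pd.DataFrame, test: str, reference: str,
                      pathway_pair: tuple[str, str],
                      metric: str) -> BiasEstimate:
    """Full Δlog -> ΔΔlog chain from a tidy per-assay agonism table."""
    sub = agonism[agonism["metric"] == metric]
    dlog = delta_log_table(sub, test, reference)
    p1 = dlog[dlog["pathway"] == pathway_pair[0]].set_index("assay_id")["dlog"]
    p2 = dlog[dlog["pathway"] == pathway_pair[1]].set_index("assay_id")["dlog"]
    joined = pd.DataFrame({"p1": p1, "p2": p2}).dropna()
    if joined.empty:
        raise ValueError(
            f"no assays with both pathways for {test!r} vs {reference!r}")
    return ddelta_log(joined["p1"].to_numpy(), joined["p2"].to_numpy(),
                      test_ligand=test, reference_ligand=reference,
                      pathway_pair=pathway_pair, metric=metric,
                      assay_ids=joined.index.tolist())


def ktau_bias(ktau_table: pd.DataFrame, test: str, reference: str,
              pathway_pair: tuple[str, str]) -> BiasEstimate:
    """ΔΔlog kτ bias factor from per-assay kinetic efficacies.

    ``ktau_table`` needs columns ligand, pathway, assay_id, ktau, holding
    the initial-rate efficacy fitted at a single saturating agonist
    concentration.  Non-positive kτ rows (non-responding wells) are
    excluded with a warning and the pairing re-checked.
    """
    required = {"ligand", "pathway", "assay_id", "ktau"}
    missing = required - set(ktau_table.columns)
    if missing:
        raise ValueError(f"ktau table missing columns: {sorted(missing)}")
    bad = ktau_table["ktau"] <= 0
    if bad.any():
        dropped = ktau_table.loc[bad, ["ligand", "pathway", "assay_id"]]
        warnings.warn(
            f"excluding {bad.sum()} non-positive ktau value(s): "
            f"{dropped.to_dict('records')}", stacklevel=2)
        ktau_table = ktau_table.loc[~bad]
    agonism = ktau_table.assign(metric="log_ktau",
                                value=np.log10(ktau_table["ktau"]))
    return bias_from_agonism(agonism, test, reference, pathway_pair,
                             metric="log_ktau")


@dataclass(frozen=True)
class PairedTTest:
    """Paired two-sided t-test result; ``degenerate`` marks zero
    within-pair variance (p collapses to 0 or 1 exactly)."""

    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_compare(values_a, values_b) -> PairedTTest:
    """Standard paired t-test on per-assay values.

    Wraps the scipy routine, defining the zero-variance degenerate cases
    explicitly: identical vectors give t = 0, p = 1; a constant non-zero
    shift gives t = +/-inf, p = 0 (both flagged ``degenerate``).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and the same length")
    if a.size < 2:
        raise ValueError("paired t-test needs n >= 2 pairs")
    diff = a - b
    df = a.size - 1
    if np.std(diff, ddof=1) == 0:
        if np.all(diff == 0):
            return PairedTTest(t=0.0, df=df, p=1.0, degenerate=True)
        sign = math.copysign(1.0, float(np.mean(diff)))
        return PairedTTest(t=sign * math.inf, df=df, p=0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTTest(t=float(res.statistic), df=df, p=float(res.pvalue))
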