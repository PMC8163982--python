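"""Synthetic plate-assay generator with known ground truth.

Emulates the structure of kinetic transducer-recruitment experiments
(split-luciferase complementation, DERET internalisation, FRET imaging):
a short baseline read, agonist addition, then a stimulation window read
at fixed intervals, alongside agonist-free vehicle wells whose slow
signal drift the downstream preprocessing must cancel.

The dimensionless agonist response ``R(t)`` follows one of two kinetic
shapes, scaled by fractional receptor occupancy ``s = c / (c + EC50)``:

* ``one_phase``   -- ``R(t) = emax_frac * s * (1 - exp(-k t))``
* ``rise_and_fall`` -- ``R(t) = A * (exp(-k1 t) - exp(-k2 t))`` with the
  amplitude ``A`` chosen so the curve's *peak* equals ``emax_frac * s``.

Raw well signals compose the response multiplicatively with a per-well
baseline, a linear drift shared by all wells (vehicle included), and
multiplicative Gaussian noise:

    signal(t) = B_w * (1 + drift_slope * t) * (1 + R(t - t_add)) * (1 + eps)

so that dividing by the per-well baseline mean and then by the vehicle
mean recovers ``R(t)`` exactly in the noiseless limit.  Identical seeds
produce bit-identical panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .traces import WellTrace, TracePanel

__all__ = [
    "SimTruth",
    "NoiseModel",
    "PlateDesign",
    "simulate_response",
    "simulate_panel",
    "simulate_experiment",
    "write_truth_sidecar",
    "reference_profiles",
]


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth pharmacology for one ligand/pathway combination.

    Parameters
    ----------
    pec50 : float
        Negative log10 of the half-maximal concentration in molar.
    emax_frac : float
        Maximal response as a fraction of the reference full agonist
        (1.0 = full agonist); expressed in units of the baseline signal.
    kinetic_model : {"one_phase", "rise_and_fall"}
    k : float
        One-phase association rate constant (1/min).
    k1, k2 : float
        Rise-and-fall decline and rise rate constants (1/min), k2 > k1 >= 0.
    rate_scaling : {"constant", "occupancy"}
        "occupancy" multiplies the rate constants by fractional occupancy,
        producing concentration-dependent kinetics as seen in
        internalisation time courses; "constant" (default) keeps rates
        concentration-independent.
    """

    ligand_name: str
    pathway: str
    pec50: float
    emax_frac: float
    kinetic_model: Literal["one_phase", "rise_and_fall"] = "one_phase"
    k: float | None = None
    k1: float | None = None
    k2: float | None = None
    rate_scaling: Literal["constant", "occupancy"] = "constant"

    def __post_init__(self) -> None:
        if not 4.0 <= self.pec50 <= 12.0:
            raise ValueError(f"pec50 must lie in [4, 12], got {self.pec50}")
        if self.emax_frac < 0:
            raise ValueError("emax_frac must be >= 0")
        if self.kinetic_model == "one_phase":
            if self.k is None or self.k <= 0:
                raise ValueError("one_phase requires k > 0")
        elif self.kinetic_model == "rise_and_fall":
            if self.k1 is None or self.k2 is None:
                raise ValueError("rise_and_fall requires k1 and k2")
            if not (self.k2 > self.k1 >= 0):
                raise ValueError("rise_and_fall requires k2 > k1 >= 0")
        else:  # pragma: no cover - guarded by Literal
            raise ValueError(f"unknown kinetic model {self.kinetic_model!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative noise, baseline scatter, and linear signal drift.

    ``drift_slope`` is the fractional change of the baseline per minute and
    applies to every well, vehicle wells included; a negative slope makes
    vehicle AUCs negative, the situation vehicle correction exists for.
    """

    cv_multiplicative: float = 0.05
    drift_slope: float = -0.002
    baseline_mean: float = 10_000.0
    baseline_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_multiplicative < 0 or self.baseline_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")

    @classmethod
    def noiseless(cls, drift_slope: float = 0.0, seed: int = 0) -> "NoiseModel":
        return cls(cv_multiplicative=0.0, drift_slope=drift_slope,
                   baseline_cv=0.0, seed=seed)


@dataclass(frozen=True)
class PlateDesign:
    """Plate layout and read schedule for one simulated experiment."""

    concentration_grid: tuple[float, ...]
    n_replicate_assays: int = 6
    baseline_window: float = 5.0
    stim_window: float = 30.0
    sampling_interval: float = 0.5
    vehicle_wells_per_assay: int = 3
    technical_replicates: int = 3
    blank_wells: int = 0
    dialect: Literal["nanobit", "deret", "fret"] = "nanobit"

    def __post_init__(self) -> None:
        if len(self.concentration_grid) == 0:
            raise ValueError("empty concentration grid")
        if any(c < 0 for c in self.concentration_grid):
            raise ValueError("negative concentration in grid")
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be > 0")
        if self.baseline_window <= 0 or self.stim_window <= 0:
            raise ValueError("baseline and stimulation windows must be > 0")
        for window, name in ((self.baseline_window, "baseline"),
                             (self.stim_window, "stimulation")):
            n = window / self.sampling_interval
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"sampling interval must divide the {name} window")
        if self.vehicle_wells_per_assay < 1:
            raise ValueError("need at least one vehicle well per assay")
        if self.technical_replicates < 1:
            raise ValueError("need at least one technical replicate well")

    @classmethod
    def around_pec50(cls, pec50: float, n_points: int = 10, span: float = 2.0,
                     **kwargs) -> "PlateDesign":
        """Log-spaced grid of ``n_points`` spanning ``pec50 +/- span``."""
        grid = np.logspace(-(pec50 + span), -(pec50 - span), n_points)
        return cls(concentration_grid=tuple(grid), **kwargs)

    @property
    def times(self) -> np.ndarray:
        """Shared read schedule, t=0 at the first baseline read."""
        total = self.baseline_window + self.stim_window
        n = int(round(total / self.sampling_interval))
        return np.linspace(0.0, total, n + 1)


def _occupancy(concentration: float, pec50: float) -> float:
    if concentration == 0:
        return 0.0
    ec50 = 10.0 ** (-pec50)
    return concentration / (concentration + ec50)


def rise_and_fall_peak_time(k1: float, k2: float) -> float:
    """Time of the maximum of exp(-k1 t) - exp(-k2 t), from dR/dt = 0."""
    if k1 == 0:
        return np.inf
    return np.log(k2 / k1) / (k2 - k1)


def simulate_response(truth: SimTruth, concentration: float,
                      times: Sequence[float]) -> np.ndarray:
    """Noiseless dimensionless response R(t) at one concentration.

    ``times`` are minutes since agonist addition (non-negative, increasing).
    """
    t = np.asarray(times, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
        raise ValueError("times must be non-negative and strictly increasing")
    if concentration < 0:
        raise ValueError("negative concentration")
    s = _occupancy(concentration, truth.pec50)
    amplitude = truth.emax_frac * s
    if amplitude == 0:
        return np.zeros_like(t)
    scale = s if truth.rate_scaling == "occupancy" else 1.0
    if truth.kinetic_model == "one_phase":
        k = truth.k * scale
        return amplitude * (1.0 - np.exp(-k * t))
    k1, k2 = truth.k1 * scale, truth.k2 * scale
    if k1 == k2:
        raise ValueError("degenerate rise_and_fall: k1 == k2")
    if k1 == 0:
        d = amplitude  # peak is the plateau
    else:
        t_peak = rise_and_fall_peak_time(k1, k2)
        d = amplitude / (np.exp(-k1 * t_peak) - np.exp(-k2 * t_peak))
    return d * (np.exp(-k1 * t) - np.exp(-k2 * t))


def _well_signal(rng: np.random.Generator, noise: NoiseModel,
                 times: np.ndarray, response: np.ndarray) -> np.ndarray:
    b = noise.baseline_mean
    if noise.baseline_cv > 0:
        b = rng.normal(noise.baseline_mean,
                       noise.baseline_cv * noise.baseline_mean)
        b = max(b, 0.05 * noise.baseline_mean)  # keep baselines physical
    signal = b * (1.0 + noise.drift_slope * times) * (1.0 + response)
    if noise.cv_multiplicative > 0:
        signal = signal * (1.0 + rng.normal(0.0, noise.cv_multiplicative,
                                            size=times.shape))
    return signal


def simulate_panel(truths: Sequence[SimTruth], design: PlateDesign,
                   noise: NoiseModel, assay_id: str = "assay1",
                   rng: np.random.Generator | None = None) -> TracePanel:
    """Simulate one assay replicate (one plate) as a :class:`TracePanel`.

    Each (truth, concentration) pair gets ``design.technical_replicates``
    agonist wells (averaged downstream within the assay, as technical
    replicates are in practice); vehicle and blank wells are appended
    after them.  With ``rng`` unset, a fresh
    generator is seeded from ``noise.seed`` so identical inputs produce
    bit-identical panels.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    times = design.times
    t_add = design.baseline_window
    stim_times = times[times >= t_add] - t_add
    wells: list[WellTrace] = []
    idx = 1
    for truth in truths:
        for conc in design.concentration_grid:
            r = np.zeros_like(times)
            r[times >= t_add] = simulate_response(truth, conc, stim_times)
            for _ in range(design.technical_replicates):
                wells.append(WellTrace(
                    well_id=f"W{idx:03d}", role="agonist",
                    ligand=truth.ligand_name, concentration=float(conc),
                    readout=truth.pathway, times=times,
                    signal=_well_signal(rng, noise, times, r)))
                idx += 1
    for _ in range(design.vehicle_wells_per_assay):
        wells.append(WellTrace(
            well_id=f"W{idx:03d}", role="vehicle", ligand=None,
            concentration=None, readout=truths[0].pathway if truths else "",
            times=times,
            signal=_well_signal(rng, noise, times, np.zeros_like(times))))
        idx += 1
    for _ in range(design.blank_wells):
        # blank wells (e.g. fluorescein without cells): flat signal, no drift
        b = np.full_like(times, noise.baseline_mean)
        if noise.cv_multiplicative > 0:
            b = b * (1.0 + rng.normal(0.0, noise.cv_multiplicative,
                                      size=times.shape))
        wells.append(WellTrace(
            well_id=f"W{idx:03d}", role="blank", ligand=None,
            concentration=None, readout=truths[0].pathway if truths else "",
            times=times, signal=b))
        idx += 1
    return TracePanel(wells=wells, baseline_end=design.baseline_window,
                      stim_end=design.baseline_window + design.stim_window,
                      assay_id=assay_id)


def simulate_experiment(truths: Sequence[SimTruth], design: PlateDesign,
                        noise: NoiseModel) -> list[TracePanel]:
    """Simulate ``design.n_replicate_assays`` independent assay replicates.

    Per-assay generators are spawned deterministically from ``noise.seed``.
    """
    root = np.random.SeedSequence(noise.seed)
    children = root.spawn(design.n_replicate_assays)
    return [
        simulate_panel(truths, design, noise, assay_id=f"assay{i + 1}",
                       rng=np.random.default_rng(child))
        for i, child in enumerate(children)
    ]


def write_truth_sidecar(path, truths: Sequence[SimTruth],
                        design: PlateDesign, noise: NoiseModel) -> None:
    """JSON sidecar recording the generating parameters of a simulation."""
    payload = {
        "truths": [asdict(t) for t in truths],
        "design": {**asdict(design),
                   "concentration_grid": list(design.concentration_grid)},
        "noise": asdict(noise),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


# --------------------------------------------------------------------------
# Published mean pharmacological parameters for the GLP-1/glucagon/OXM
# ligand panel this package was developed around.  pEC50 and Emax (% of the
# pathway's full agonist) come from 3-parameter fits of AUC data; the
# association rate constant is the one-phase K@[max] for G-protein
# (mini-Gs) and internalisation readouts, and the rise rate k2 of the
# bi-exponential for beta-arrestin-2, whose decline rate k1 is not
# reported and defaults to 0.05/min here.  These rows serve as default
# simulation truths for calibration studies.
_REFERENCE_ROWS: list[dict] = [
    # receptor, ligand, pathway, pec50, emax_pct, rate, model, reference ligand
    dict(receptor="GLP-1R", ligand="GLP-1", pathway="mini-Gs",
         pec50=7.7, emax_pct=105, rate=0.30, model="one_phase", reference="GLP-1"),
    dict(receptor="GLP-1R", ligand="GLP-1-AIB2", pathway="mini-Gs",
         pec50=7.9, emax_pct=96, rate=0.21, model="one_phase", reference="GLP-1"),
    dict(receptor="GLP-1R", ligand="GLP-1", pathway="barr2",
         pec50=7.3, emax_pct=100, rate=1.25, model="rise_and_fall", reference="GLP-1"),
    dict(receptor="GLP-1R", ligand="GLP-1-AIB2", pathway="barr2",
         pec50=7.7, emax_pct=68, rate=0.82, model="rise_and_fall", reference="GLP-1"),
    dict(receptor="GCGR", ligand="GCG", pathway="mini-Gs",
         pec50=6.7, emax_pct=100, rate=0.17, model="one_phase", reference="GCG"),
    dict(receptor="GCGR", ligand="GCG-AIB2", pathway="mini-Gs",
         pec50=6.7, emax_pct=54, rate=0.11, model="one_phase", reference="GCG"),
    dict(receptor="GCGR", ligand="GCG-H3", pathway="mini-Gs",
         pec50=6.8, emax_pct=66, rate=0.13, model="one_phase", reference="GCG"),
    dict(receptor="GCGR", ligand="GCG-AIB2H3", pathway="mini-Gs",
         pec50=7.0, emax_pct=74, rate=0.13, model="one_phase", reference="GCG"),
    dict(receptor="GCGR", ligand="GCG", pathway="barr2",
         pec50=6.1, emax_pct=100, rate=0.89, model="rise_and_fall", reference="GCG"),
    dict(receptor="GCGR", ligand="GCG-AIB2", pathway="barr2",
         pec50=6.2, emax_pct=25, rate=0.29, model="rise_and_fall", reference="GCG"),
    dict(receptor="GCGR", ligand="GCG-H3", pathway="barr2",
         pec50=6.3, emax_pct=54, rate=0.51, model="rise_and_fall", reference="GCG"),
    dict(receptor="GCGR", ligand="GCG-AIB2H3", pathway="barr2",
         pec50=6.6, emax_pct=53, rate=0.56, model="rise_and_fall", reference="GCG"),
    dict(receptor="GLP-1R", ligand="SRB103H", pathway="mini-Gs",
         pec50=7.1, emax_pct=103, rate=0.93, model="one_phase", reference="SRB103H"),
    dict(receptor="GLP-1R", ligand="SRB103Q", pathway="mini-Gs",
         pec50=7.3, emax_pct=97, rate=0.70, model="one_phase", reference="SRB103H"),
    dict(receptor="GLP-1R", ligand="SRB103H", pathway="barr2",
         pec50=6.4, emax_pct=100, rate=0.37, model="rise_and_fall", reference="SRB103H"),
    dict(receptor="GLP-1R", ligand="SRB103Q", pathway="barr2",
         pec50=6.7, emax_pct=60, rate=0.39, model="rise_and_fall", reference="SRB103H"),
    dict(receptor="GCGR", ligand="SRB103H", pathway="mini-Gs",
         pec50=8.1, emax_pct=100, rate=0.14, model="one_phase", reference="SRB103H"),
    dict(receptor="GCGR", ligand="SRB103Q", pathway="mini-Gs",
         pec50=7.7, emax_pct=83, rate=0.13, model="one_phase", reference="SRB103H"),
    dict(receptor="GCGR", ligand="SRB103H", pathway="barr2",
         pec50=7.5, emax_pct=100, rate=0.81, model="rise_and_fall", reference="SRB103H"),
    dict(receptor="GCGR", ligand="SRB103Q", pathway="barr2",
         pec50=7.3, emax_pct=77, rate=0.71, model="rise_and_fall", reference="SRB103H"),
    # DERET internalisation: absolute Emax in ratio*min units 3.0 vs 2.7,
    # expressed here as a fraction of the reference ligand's maximum.
    dict(receptor="GLP-1R", ligand="SRB103H", pathway="internalisation",
         pec50=7.7, emax_pct=100, rate=0.14, model="one_phase", reference="SRB103H"),
    dict(receptor="GLP-1R", ligand="SRB103Q", pathway="internalisation",
         pec50=7.7, emax_pct=90, rate=0.50, model="one_phase", reference="SRB103H"),
]

DEFAULT_ARRESTIN_K1 = 0.05  # 1/min, decline rate where only the rise rate is reported


def reference_profiles() -> pd.DataFrame:
    """Literature-derived mean parameter table used as simulation truths."""
    return pd.DataFrame(_REFERENCE_ROWS)


def truth_from_profile(row: dict | pd.Series,
                       rate_scaling: str = "constant") -> SimTruth:
    """Build a :class:`SimTruth` from a reference-profile row."""
    common = dict(ligand_name=row["ligand"], pathway=row["pathway"],
                  pec50=float(row["pec50"]),
                  emax_frac=float(row["emax_pct"]) / 100.0,
                  rate_scaling=rate_scaling)
    if row["model"] == "one_phase":
        return SimTruth(kinetic_model="one_phase", k=float(row["rate"]),
                        **common)
    return SimTruth(kinetic_model="rise_and_fall", k1=DEFAULT_ARRESTIN_K1,
                    k2=float(row["rate"]), **common)
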