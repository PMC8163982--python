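"""Raw well traces and their normalisation into dimensionless responses.

The preprocessing chain mirrors the standard kinetic plate-reader
workflow: each well is first expressed relative to its own pre-stimulation
baseline (F/F0), then ratioed at every time point to the mean vehicle
well to cancel drift, giving the dimensionless response

    R(t) = well(t) / vehicle(t) - 1

which is zero for a well indistinguishable from vehicle.  Scalar
summaries (trapezoidal AUC over the stimulation window, with the vehicle
AUC subtracted) feed the concentration-response fits downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "WellTrace",
    "TracePanel",
    "ProcessedTrace",
    "baseline_normalise",
    "vehicle_correct",
    "auc",
    "subtract_vehicle_auc",
    "deret_ratio",
    "process_panel",
]


@dataclass(frozen=True)
class WellTrace:
    """One well's time series with its role metadata.

    ``times`` are minutes from the first read; ``signal`` is in raw
    reader units (or a dimensionless ratio after normalisation).
    Vehicle and blank wells carry no ligand or concentration.
    """

    well_id: str
    role: Literal["agonist", "vehicle", "blank"]
    ligand: str | None
    concentration: float | None
    readout: str
    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "signal",
                           np.asarray(self.signal, dtype=float))
        if self.times.shape != self.signal.shape:
            raise ValueError(f"well {self.well_id}: times/signal length mismatch")
        if self.times.size >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"well {self.well_id}: times not strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(f"well {self.well_id}: non-finite signal")
        if self.role in ("vehicle", "blank") and (
                self.ligand is not None or self.concentration is not None):
            raise ValueError(
                f"well {self.well_id}: {self.role} wells must not carry a "
                "ligand or concentration")


@dataclass(frozen=True)
class TracePanel:
    """All wells of one assay replicate on a shared time grid.

    ``baseline_end`` is the time of agonist addition; ``stim_end`` the end
    of the stimulation window (both minutes from the first read).
    """

    wells: list[WellTrace]
    baseline_end: float
    stim_end: float
    assay_id: str = "assay1"

    def __post_init__(self) -> None:
        if not self.wells:
            raise ValueError("panel has no wells")
        if not self.baseline_end < self.stim_end:
            raise ValueError("baseline_end must precede stim_end")
        grid = self.wells[0].times
        for w in self.wells[1:]:
            if w.times.shape != grid.shape or not np.array_equal(w.times, grid):
                raise ValueError(
                    f"well {w.well_id} is not on the shared time grid")
        if not any(w.role == "vehicle" for w in self.wells):
            raise ValueError(f"assay {self.assay_id!r} has no vehicle well")

    @property
    def times(self) -> np.ndarray:
        return self.wells[0].times

    def vehicle_mean(self) -> WellTrace:
        """Pointwise mean of all vehicle wells, as a pseudo-well."""
        vehicles = [w for w in self.wells if w.role == "vehicle"]
        mean = np.mean([w.signal for w in vehicles], axis=0)
        return WellTrace(well_id="vehicle_mean", role="vehicle", ligand=None,
                         concentration=None, readout=vehicles[0].readout,
                         times=vehicles[0].times, signal=mean)


@dataclass(frozen=True)
class ProcessedTrace:
    """Baseline- and vehicle-corrected dimensionless response.

    ``times`` are stimulation-relative (t = 0 at agonist addition;
    baseline samples, if retained, carry negative times).  In the
    noiseless limit ``response(0) = 0`` by construction.
    """

    ligand: str | None
    concentration: float | None
    readout: str
    times: np.ndarray
    response: np.ndarray
    assay_id: str = "assay1"
    well_id: str = ""
    role: str = "agonist"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "response",
                           np.asarray(self.response, dtype=float))
        if not np.all(np.isfinite(self.response)):
            raise ValueError("non-finite response after correction")

    def stim_times(self) -> np.ndarray:
        return self.times[self.times >= 0]

    def stim_response(self) -> np.ndarray:
        return self.response[self.times >= 0]


def baseline_normalise(trace: WellTrace, baseline_end: float) -> WellTrace:
    """Divide a well by its mean signal over the baseline window (F/F0).

    The baseline window is ``[first read, baseline_end]`` and must hold at
    least two samples; a non-positive baseline mean signals corrupt input.
    """
    mask = trace.times <= baseline_end
    if mask.sum() < 2:
        raise ValueError(
            f"well {trace.well_id}: fewer than 2 samples in baseline window")
    f0 = trace.signal[mask].mean()
    if f0 <= 0:
        raise ValueError(
            f"well {trace.well_id}: non-positive baseline mean ({f0:g})")
    return replace(trace, signal=trace.signal / f0)


def vehicle_correct(trace: WellTrace, vehicle_mean: WellTrace,
                    mode: Literal["divide", "subtract"] = "divide",
                    stim_start: float = 0.0) -> ProcessedTrace:
    """Correct an F/F0 trace against the mean vehicle F/F0 trace.

    ``divide`` (default) returns ``trace/vehicle - 1``, which exactly
    cancels multiplicative drift; ``subtract`` returns ``trace - vehicle``.
    Output times are shifted so t = 0 falls at ``stim_start``.
    """
    if (trace.times.shape != vehicle_mean.times.shape
            or not np.array_equal(trace.times, vehicle_mean.times)):
        raise ValueError(
            f"well {trace.well_id}: vehicle trace is not on the same time grid")
    if mode == "divide":
        if np.any(vehicle_mean.signal <= 0):
            raise ValueError("vehicle mean is non-positive at some time point")
        response = trace.signal / vehicle_mean.signal - 1.0
    elif mode == "subtract":
        response = trace.signal - vehicle_mean.signal
    else:
        raise ValueError(f"unknown vehicle-correction mode {mode!r}")
    return ProcessedTrace(ligand=trace.ligand,
                          concentration=trace.concentration,
                          readout=trace.readout,
                          times=trace.times - stim_start,
                          response=response,
                          well_id=trace.well_id, role=trace.role)


def auc(trace: ProcessedTrace, t0: float, t1: float) -> float:
    """Signed trapezoidal integral of the response over ``[t0, t1]``.

    Endpoints inside the sampled support are linearly interpolated.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    t, y = trace.times, trace.response
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError(f"[{t0}, {t1}] outside trace support [{t[0]}, {t[-1]}]")
    inner = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inner], [t1]))
    yy = np.concatenate(([np.interp(t0, t, y)], y[inner], [np.interp(t1, t, y)]))
    return float(np.trapezoid(yy, tt))


def subtract_vehicle_auc(agonist_aucs: Mapping[str, float] | Sequence[float],
                         vehicle_auc: float):
    """Subtract the (mean) vehicle AUC from every agonist AUC.

    Baseline drift commonly drives the vehicle AUC negative; subtracting
    it re-zeros the scale so vehicle itself maps to 0.  Accepts a mapping
    (returned as a dict) or a sequence (returned as an ndarray).
    """
    if isinstance(agonist_aucs, Mapping):
        return {k: v - vehicle_auc for k, v in agonist_aucs.items()}
    return np.asarray(agonist_aucs, dtype=float) - vehicle_auc


def deret_ratio(em620: WellTrace, em520: WellTrace,
                blank620: float, blank520: float) -> WellTrace:
    """Blank-subtracted 620/520 nm emission ratio for a DERET well.

    Blanks come from wells with acceptor fluorophore but no cells; the
    ratio rises as surface donor is internalised away from the acceptor.
    """
    if (em620.times.shape != em520.times.shape
            or not np.array_equal(em620.times, em520.times)):
        raise ValueError("620 and 520 nm traces are not on the same grid")
    denom = em520.signal - blank520
    if np.any(denom <= 0):
        raise ValueError("blank-subtracted 520 nm signal is non-positive")
    ratio = (em620.signal - blank620) / denom
    return replace(em620, signal=ratio,
                   readout=em620.readout or "deret_ratio")


def process_panel(panel: TracePanel,
                  mode: Literal["divide", "subtract"] = "divide",
                  keep_baseline: bool = False) -> list[ProcessedTrace]:
    """Baseline-normalise and vehicle-correct every non-blank well.

    Vehicle wells are averaged pointwise (after their own baseline
    normalisation) before correction; agonist and vehicle wells are both
    returned so vehicle AUCs remain available downstream.  Unless
    ``keep_baseline`` is set, samples before agonist addition are dropped
    and times are re-origined to the addition.
    """
    norm = {w.well_id: baseline_normalise(w, panel.baseline_end)
            for w in panel.wells if w.role != "blank"}
    vehicles = [norm[w.well_id] for w in panel.wells if w.role == "vehicle"]
    vmean = WellTrace(well_id="vehicle_mean", role="vehicle", ligand=None,
                      concentration=None, readout=vehicles[0].readout,
                      times=vehicles[0].times,
                      signal=np.mean([v.signal for v in vehicles], axis=0))
    out = []
    for w in panel.wells:
        if w.role == "blank":
            continue
        p = vehicle_correct(norm[w.well_id], vmean, mode=mode,
                            stim_start=panel.baseline_end)
        if not keep_baseline:
            keep = p.times >= 0
            p = ProcessedTrace(ligand=p.ligand, concentration=p.concentration,
                               readout=p.readout, times=p.times[keep],
                               response=p.response[keep],
                               assay_id=panel.assay_id, well_id=p.well_id,
                               role=p.role)
        else:
            p = ProcessedTrace(ligand=p.ligand, concentration=p.concentration,
                               readout=p.readout, times=p.times,
                               response=p.response, assay_id=panel.assay_id,
                               well_id=p.well_id, role=p.role)
        out.append(p)
    return out
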