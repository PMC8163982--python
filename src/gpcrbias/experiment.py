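"""End-to-end bias analysis of a kinetic plate experiment.

:class:`BiasExperiment` is the top-level model object: build it from a
set of :class:`~gpcrbias.traces.TracePanel` assay replicates (or a tidy
long-format DataFrame), call :meth:`fit`, and read estimates off the
returned :class:`BiasExperimentResults`.

The fitted pipeline follows the standard kinetic-assay workflow:
baseline normalisation, vehicle correction, AUC over the stimulation
window with vehicle-AUC subtraction, per-assay logistic fits of AUC vs
concentration, Emax normalisation to the reference full agonist, and
the Δlog -> ΔΔlog bias chain on the log(Emax/EC50) scale.  Optionally
the kinetic kτ route is run as well: one-phase or rise-and-fall fits of
the single-maximal-concentration trace per pathway, with ΔΔlog kτ bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .traces import TracePanel, ProcessedTrace, process_panel, auc, \
    subtract_vehicle_auc
from .models import LogisticModel, OnePhaseModel, RiseAndFallModel, \
    normalise_emax, KineticResults, LogisticResults
from .bias import BiasEstimate, log_max_ec50, bias_from_agonism, ktau_bias

__all__ = ["BiasExperiment", "BiasExperimentResults"]

KTAU_DEFINITION = ("ktau = initial rate of the fitted response at t=0 "
                   "(one_phase: ss*k; rise_and_fall: d*(k2-k1))")


def _choose_kinetic_model(times: np.ndarray, response: np.ndarray) -> str:
    """Deterministic shape heuristic for the kinetic model class.

    A trace whose (smoothed) maximum falls well inside the window and
    whose final value has dropped clearly below that maximum is treated
    as rise-and-fall; anything else as one-phase association.  A short
    moving average suppresses single-read noise spikes that would
    otherwise masquerade as an interior peak.
    """
    if response.size < 6:
        return "one_phase"
    width = min(5, response.size)
    smooth = np.convolve(response, np.ones(width) / width, mode="valid")
    t_smooth = times[width - 1:]
    i_max = int(np.argmax(smooth))
    y_max = smooth[i_max]
    if y_max <= 0:
        return "one_phase"
    interior = t_smooth[i_max] < 0.8 * t_smooth[-1]
    declined = smooth[-1] < 0.85 * y_max
    return "rise_and_fall" if (interior and declined) else "one_phase"


@dataclass
class BiasExperiment:
    """Two-pathway bias analysis model.

    Parameters
    ----------
    panels : sequence of TracePanel
        Assay replicates; wells from the two pathways are matched by
        their ``readout`` label and assays by ``assay_id``.
    reference : str
        Reference (full agonist) ligand; Δlog values are taken against
        it within each assay.
    pathways : (str, str)
        Ordered pathway pair; positive ΔΔlog = bias toward the first.
    metrics : sequence of {"log_max_ec50", "log_ktau"}
    vehicle_mode : {"divide", "subtract"}
        Per-time-point vehicle correction convention.
    kinetic_models : mapping pathway -> {"one_phase", "rise_and_fall", "auto"}
        Model class for the kτ route (default "auto": shape heuristic).
    max_concentration : float, optional
        Saturating concentration for the kτ route; defaults to the
        highest concentration present.
    """

    panels: Sequence[TracePanel]
    reference: str
    pathways: tuple[str, str]
    metrics: Sequence[str] = ("log_max_ec50",)
    vehicle_mode: Literal["divide", "subtract"] = "divide"
    kinetic_models: dict | None = None
    max_concentration: float | None = None
    bottom_floor: float | None = 0.0

    def __post_init__(self) -> None:
        if len(self.pathways) != 2:
            raise ValueError("pathway pair must have exactly 2 members")
        unknown = set(self.metrics) - {"log_max_ec50", "log_ktau"}
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        ligands = {w.ligand for p in self.panels for w in p.wells
                   if w.role == "agonist"}
        if self.reference not in ligands:
            raise ValueError(
                f"reference ligand {self.reference!r} not present in data "
                f"(found: {sorted(l for l in ligands if l)})")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, baseline_end: float,
                       stim_end: float, **kwargs) -> "BiasExperiment":
        """Build from a tidy long-format plate table (see io module)."""
        from .io import panels_from_dataframe
        panels = panels_from_dataframe(frame, baseline_end=baseline_end,
                                       stim_end=stim_end)
        return cls(panels=panels, **kwargs)

    # -- pipeline stages ----------------------------------------------------

    def _qc_row(self, panel: TracePanel, well, corrected_auc: float) -> dict:
        base = well.times <= panel.baseline_end
        # drift: agonist wells only expose their baseline window; vehicle
        # and blank wells drift over the whole read
        window = np.ones_like(base) if well.role != "agonist" else base
        slope = float(np.polyfit(
            well.times[window],
            well.signal[window] / well.signal[window].mean(),
            1)[0]) if window.sum() >= 2 else np.nan
        return dict(assay_id=panel.assay_id, well_id=well.well_id,
                    role=well.role, ligand=well.ligand,
                    concentration=well.concentration, readout=well.readout,
                    baseline_mean=float(well.signal[base].mean()),
                    drift_per_min=slope, corrected_auc=corrected_auc)

    def _aucs(self):
        """Per-well vehicle-subtracted AUCs plus processed traces and QC."""
        stim_len = self.panels[0].stim_end - self.panels[0].baseline_end
        auc_rows, qc_rows, processed = [], [], []
        for panel in self.panels:
            traces = process_panel(panel, mode=self.vehicle_mode)
            processed.extend(traces)
            raw_auc = {tr.well_id: auc(tr, 0.0, stim_len) for tr in traces}
            veh = [raw_auc[tr.well_id] for tr in traces if tr.role == "vehicle"]
            veh_mean = float(np.mean(veh))
            corrected = subtract_vehicle_auc(raw_auc, veh_mean)
            well_by_id = {w.well_id: w for w in panel.wells}
            for tr in traces:
                qc_rows.append(self._qc_row(panel, well_by_id[tr.well_id],
                                            corrected[tr.well_id]))
                if tr.role != "agonist":
                    continue
                auc_rows.append(dict(
                    assay_id=panel.assay_id, ligand=tr.ligand,
                    pathway=tr.readout, concentration=tr.concentration,
                    auc=corrected[tr.well_id]))
        return (pd.DataFrame(auc_rows), pd.DataFrame(qc_rows), processed)

    def _logistic_route(self, aucs: pd.DataFrame):
        """Per-assay logistic fits of AUC vs concentration, normalised."""
        fit_rows, agonism_rows = [], []
        fits_store: dict = {}
        for (assay, pathway), grp in aucs.groupby(["assay_id", "pathway"]):
            fits: dict[str, LogisticResults] = {}
            for ligand, sub in grp.groupby("ligand"):
                # technical replicate wells average into one point per
                # concentration before fitting
                mean_auc = sub.groupby("concentration")["auc"].mean()
                fits[ligand] = LogisticModel(
                    mean_auc.index.to_numpy(), mean_auc.to_numpy()).fit(
                        bottom_floor=self.bottom_floor)
            fits = normalise_emax(fits, reference=self.reference)
            for ligand, f in fits.items():
                fits_store[(assay, pathway, ligand)] = f
                fit_rows.append(dict(
                    assay_id=assay, pathway=pathway, ligand=ligand,
                    bottom=f.bottom, top=f.top, pec50=f.pec50,
                    emax_pct=f.emax_pct, rss=f.rss, converged=f.converged))
                if f.converged and f.emax_pct is not None and f.emax_pct > 0:
                    agonism_rows.append(dict(
                        ligand=ligand, pathway=pathway, assay_id=assay,
                        metric="log_max_ec50",
                        value=log_max_ec50(f.emax_pct, f.pec50)))
        return pd.DataFrame(fit_rows), pd.DataFrame(agonism_rows), fits_store

    def _kinetic_route(self, processed: list[ProcessedTrace]):
        """kτ at the single maximal concentration, per ligand and assay."""
        agonist = [tr for tr in processed if tr.role == "agonist"]
        cmax_by_pathway: dict[str, float] = {}
        for tr in agonist:
            cur = cmax_by_pathway.get(tr.readout, -np.inf)
            cmax_by_pathway[tr.readout] = max(cur, tr.concentration)
        rows, fit_rows = [], []
        mapping = self.kinetic_models or {}
        # average technical replicate wells pointwise within each assay
        groups: dict[tuple, list] = {}
        for tr in agonist:
            cmax = (self.max_concentration if self.max_concentration
                    is not None else cmax_by_pathway[tr.readout])
            if not np.isclose(tr.concentration, cmax, rtol=1e-6):
                continue
            key = (tr.assay_id, tr.readout, tr.ligand, tr.concentration)
            groups.setdefault(key, []).append(tr)
        for (assay_id, readout, ligand, conc), reps in groups.items():
            tr = reps[0]
            t = tr.stim_times()
            y = np.mean([r.stim_response() for r in reps], axis=0)
            which = mapping.get(readout, "auto")
            if which == "auto":
                which = _choose_kinetic_model(t, y)
            model = OnePhaseModel if which == "one_phase" else RiseAndFallModel
            fit: KineticResults = model(t, y).fit()
            fit_rows.append(dict(
                assay_id=assay_id, ligand=ligand, pathway=readout,
                concentration=conc, model=fit.kinetic_model,
                ktau=fit.ktau, converged=fit.converged,
                degenerate=fit.degenerate, **fit.params))
            rows.append(dict(ligand=ligand, pathway=readout,
                             assay_id=assay_id, ktau=fit.ktau))
        return pd.DataFrame(fit_rows), pd.DataFrame(rows)

    def fit(self) -> "BiasExperimentResults":
        aucs, qc, processed = self._aucs()
        logistic_fits = agonism = pd.DataFrame()
        kinetic_fits = ktau_table = pd.DataFrame()
        estimates: list[BiasEstimate] = []
        if "log_max_ec50" in self.metrics:
            logistic_fits, agonism, _ = self._logistic_route(aucs)
        if "log_ktau" in self.metrics:
            kinetic_fits, ktau_table = self._kinetic_route(processed)
        test_ligands = sorted({w.ligand for p in self.panels for w in p.wells
                               if w.role == "agonist"
                               and w.ligand != self.reference})
        for ligand in test_ligands:
            if "log_max_ec50" in self.metrics and not agonism.empty:
                estimates.append(bias_from_agonism(
                    agonism, ligand, self.reference, self.pathways,
                    metric="log_max_ec50"))
            if "log_ktau" in self.metrics and not ktau_table.empty:
                estimates.append(ktau_bias(
                    ktau_table, ligand, self.reference, self.pathways))
        return BiasExperimentResults(
            experiment=self, aucs=aucs, qc=qc,
            logistic_fits=logistic_fits, kinetic_fits=kinetic_fits,
            agonism=agonism, bias_estimates=estimates)


@dataclass
class BiasExperimentResults:
    """Fitted tables and bias estimates from a :class:`BiasExperiment`."""

    experiment: BiasExperiment
    aucs: pd.DataFrame
    qc: pd.DataFrame
    logistic_fits: pd.DataFrame
    kinetic_fits: pd.DataFrame
    agonism: pd.DataFrame
    bias_estimates: list[BiasEstimate] = field(default_factory=list)

    @property
    def bias_table(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.bias_estimates])

    def summary(self) -> str:
        exp = self.experiment
        head = [
            "Two-pathway bias analysis",
            f"  reference ligand : {exp.reference}",
            f"  pathway pair     : {exp.pathways[0]} vs {exp.pathways[1]} "
            "(positive ΔΔlog = toward the former)",
            f"  vehicle mode     : {exp.vehicle_mode}",
            f"  {KTAU_DEFINITION}",
            f"  assays           : {len(exp.panels)}",
            "",
        ]
        body = [e.summary() + "\n" for e in self.bias_estimates] \
            or ["  (no test ligands)"]
        return "\n".join(head + body)
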