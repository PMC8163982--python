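"""Tidy plate CSV reading/writing and report bundles.

The interchange format is one long-format UTF-8 CSV with the columns

    assay_id, well_id, role, ligand, concentration_M, readout, time_min, signal

one row per well per time point, concentrations in molar, times in
minutes from the first read.  Vehicle and blank rows leave ligand and
concentration empty.  Vendor plate-reader exports are out of scope; see
:func:`vendor_converter_stub` for the columns a converter must supply.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import TracePanel, WellTrace

__all__ = [
    "PLATE_COLUMNS",
    "read_plate_csv",
    "write_plate_csv",
    "panels_from_dataframe",
    "panels_to_dataframe",
    "write_report_bundle",
    "PlateValidationError",
]

PLATE_COLUMNS = ["assay_id", "well_id", "role", "ligand", "concentration_M",
                 "readout", "time_min", "signal"]
_ROLES = {"agonist", "vehicle", "blank"}


class PlateValidationError(ValueError):
    """Raised for schema or consistency problems in a plate table."""


def panels_from_dataframe(frame: pd.DataFrame, baseline_end: float,
                          stim_end: float) -> list[TracePanel]:
    """Validate a tidy plate table and split it into per-assay panels."""
    missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise PlateValidationError(f"missing column(s): {missing}")
    bad_roles = set(frame["role"].unique()) - _ROLES
    if bad_roles:
        raise PlateValidationError(
            f"unknown role(s) {sorted(bad_roles)}; expected {sorted(_ROLES)}")
    panels = []
    for assay_id, assay in frame.groupby("assay_id", sort=True):
        wells = []
        for well_id, grp in assay.groupby("well_id", sort=True):
            grp = grp.sort_values("time_min")
            times = grp["time_min"].to_numpy(dtype=float)
            if np.unique(times).size != times.size:
                raise PlateValidationError(
                    f"assay {assay_id!r} well {well_id!r}: duplicate "
                    "(well, time) rows")
            role = grp["role"].iloc[0]
            if grp["role"].nunique() > 1:
                raise PlateValidationError(
                    f"assay {assay_id!r} well {well_id!r}: inconsistent role")
            ligand = grp["ligand"].iloc[0]
            ligand = None if pd.isna(ligand) or ligand == "" else str(ligand)
            conc = grp["concentration_M"].iloc[0]
            conc = None if pd.isna(conc) else float(conc)
            try:
                wells.append(WellTrace(
                    well_id=str(well_id), role=role, ligand=ligand,
                    concentration=conc, readout=str(grp["readout"].iloc[0]),
                    times=times,
                    signal=grp["signal"].to_numpy(dtype=float)))
            except ValueError as err:
                raise PlateValidationError(
                    f"assay {assay_id!r}: {err}") from err
        try:
            panels.append(TracePanel(wells=wells, baseline_end=baseline_end,
                                     stim_end=stim_end,
                                     assay_id=str(assay_id)))
        except ValueError as err:
            raise PlateValidationError(f"assay {assay_id!r}: {err}") from err
    if not panels:
        raise PlateValidationError("plate table contains no rows")
    return panels


def read_plate_csv(path, baseline_end: float,
                   stim_end: float) -> list[TracePanel]:
    """Read and validate a tidy plate CSV into per-assay panels."""
    frame = pd.read_csv(path, dtype={"assay_id": str, "well_id": str,
                                     "role": str, "ligand": str,
                                     "readout": str})
    frame["concentration_M"] = pd.to_numeric(frame["concentration_M"],
                                             errors="coerce") \
        if "concentration_M" in frame.columns else np.nan
    return panels_from_dataframe(frame, baseline_end=baseline_end,
                                 stim_end=stim_end)


def panels_to_dataframe(panels) -> pd.DataFrame:
    rows = []
    for panel in panels:
        for w in panel.wells:
            rows.append(pd.DataFrame({
                "assay_id": panel.assay_id, "well_id": w.well_id,
                "role": w.role, "ligand": w.ligand if w.ligand else "",
                "concentration_M": (np.nan if w.concentration is None
                                    else w.concentration),
                "readout": w.readout, "time_min": w.times,
                "signal": w.signal}))
    return pd.concat(rows, ignore_index=True)[PLATE_COLUMNS]


def write_plate_csv(path, panels) -> None:
    """Write panels to the tidy plate CSV with stable number formatting."""
    panels_to_dataframe(panels).to_csv(path, index=False,
                                       float_format="%.10g")


def write_report_bundle(outdir, results, config_echo: dict | None = None,
                        log_lines: list[str] | None = None) -> dict:
    """Write the fit tables, bias report, QC table and run log.

    Returns the mapping of logical names to written file paths.  Every
    report header records the vehicle-correction mode, the kτ definition
    and the pathway sign convention so conventions travel with the data.
    """
    from .experiment import KTAU_DEFINITION

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = results.experiment
    paths = {}

    def _csv(name: str, frame: pd.DataFrame):
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False, float_format="%.10g")
        paths[name] = p

    if not results.logistic_fits.empty:
        _csv("logistic_fits", results.logistic_fits)
    if not results.kinetic_fits.empty:
        _csv("kinetic_fits", results.kinetic_fits)
    if not results.agonism.empty:
        _csv("agonism", results.agonism)
    _csv("qc", results.qc)
    bias_records = [e.to_dict() for e in results.bias_estimates]
    bias_path = outdir / "bias_report.json"
    header = {
        "vehicle_mode": exp.vehicle_mode,
        "ktau_definition": KTAU_DEFINITION,
        "pathway_pair": list(exp.pathways),
        "sign_convention": ("positive ddlog = bias toward "
                            f"{exp.pathways[0]}"),
        "reference_ligand": exp.reference,
    }
    with open(bias_path, "w", encoding="utf-8") as fh:
        json.dump({"header": header, "estimates": bias_records}, fh, indent=2)
    paths["bias_report_json"] = bias_path
    if bias_records:
        _csv("bias_report", pd.DataFrame(
            [{k: v for k, v in r.items() if k != "per_assay_dd"}
             for r in bias_records]))
    log_path = outdir / "run_log.txt"
    with open(log_path, "w", encoding="utf-8") as fh:
        for key, value in header.items():
            fh.write(f"{key}: {value}\n")
        if config_echo:
            fh.write("config:\n")
            for key, value in config_echo.items():
                fh.write(f"  {key}: {value}\n")
        for line in log_lines or []:
            fh.write(line + "\n")
    paths["run_log"] = log_path
    return paths


def vendor_converter_stub() -> str:
    """Columns a vendor plate-reader export converter must produce."""
    return (
        "A converter from a vendor plate-reader export must emit the tidy "
        "long-format CSV with columns: " + ", ".join(PLATE_COLUMNS) + ". "
        "Concentrations in molar; time in minutes from the first read; one "
        "row per well per time point; vehicle/blank rows with empty ligand "
        "and concentration.")
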