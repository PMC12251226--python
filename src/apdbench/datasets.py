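"""Packaged study tables and report-bundle output.

The study's printed tables are shipped as versioned CSV resources:

- ``table1.csv`` — per drug condition: mean baseline APD90 (SD) and mean
  drug-induced ΔAPD90 (SEM) over trabeculae (29 unique conditions);
- ``table2.csv`` — the drug panel with nominal concentrations, trabecula
  counts and whether bath concentrations were measured;
- ``table3.csv`` — IC50 (uM) and Hill coefficients for ICaL/IKr under the
  Pharm and CiPA patch-clamp protocols, with censored ('>X') entries;
- ``table4.csv`` — the AP model roster with structure notes and printed
  reference IKs conductances where available.

Loaders return typed records and enforce the cross-table invariants; the
packaged bytes are guarded by checked-in checksums so silent curation
drift fails loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from apdbench.benchmark import (
    CUBIC_EXPONENTS,
    DeltaAPDMap,
    ErrorReport,
    ExperimentalRecord,
    SurfaceFit,
)
from apdbench.pharmacology import DrugEntry, HillParameters

__all__ = ["StudyTables", "TableValidationError", "load_study_tables",
           "write_study_tables", "write_report_bundle"]


class TableValidationError(ValueError):
    """A packaged table failed checksum or invariant validation."""


@dataclass(frozen=True)
class PanelRow:
    """One Table-2 study arm (a drug with its concentration series)."""

    drug: str
    concentrations: tuple[float, ...]
    n_trabeculae: int
    measured_concentration: bool


@dataclass(frozen=True)
class RosterRow:
    """One model of the study roster."""

    model: str
    structure: str
    endocardial_selected: bool
    tier: str
    gks_ms_per_uf: float | None
    reference: str


@dataclass(frozen=True)
class StudyTables:
    table1: tuple[ExperimentalRecord, ...]
    table2: tuple[PanelRow, ...]
    table3: Mapping[tuple[str, str], DrugEntry]  # (drug, dataset) -> entry
    table4: tuple[RosterRow, ...]

    @property
    def conditions(self) -> tuple[tuple[str, float], ...]:
        return tuple(r.condition for r in self.table1)

    def drug_conditions(self):
        from apdbench.pharmacology import DrugCondition

        return [DrugCondition(drug=d, concentration=c) for d, c in self.conditions]


_SOURCE_DIR: Path | None = None  # None -> packaged resources


def _read_packaged(name: str) -> bytes:
    if _SOURCE_DIR is not None:
        return (_SOURCE_DIR / name).read_bytes()
    return resources.files("apdbench.data").joinpath(name).read_bytes()


def _check_checksums() -> None:
    expected = json.loads(_read_packaged("checksums.json"))
    for name, digest in expected.items():
        actual = hashlib.sha256(_read_packaged(name)).hexdigest()
        if actual != digest:
            raise TableValidationError(
                f"packaged table {name} checksum mismatch: {actual} != {digest}"
            )


def _load_table1() -> tuple[ExperimentalRecord, ...]:
    import io

    df = pd.read_csv(io.BytesIO(_read_packaged("table1.csv")))
    counts = _load_table2()
    n_by_drug = {}
    for row in counts:
        n_by_drug[row.drug] = n_by_drug.get(row.drug, 0) + row.n_trabeculae
    return tuple(
        ExperimentalRecord(
            drug=r.drug,
            concentration=float(r.concentration_um),
            mean_delta_apd90=float(r.mean_delta_apd90_ms),
            sem=float(r.sem_ms),
            n_trabeculae=n_by_drug[r.drug],
            mean_baseline_apd90=float(r.baseline_apd90_ms),
            baseline_sd=float(r.baseline_sd_ms),
        )
        for r in df.itertuples()
    )


def _load_table2() -> tuple[PanelRow, ...]:
    import io

    df = pd.read_csv(io.BytesIO(_read_packaged("table2.csv")))
    rows = []
    for r in df.itertuples():
        concs = tuple(
            float(c) for c in (r.conc1_um, r.conc2_um, r.conc3_um, r.conc4_um)
            if pd.notna(c)
        )
        rows.append(PanelRow(
            drug=r.drug,
            concentrations=concs,
            n_trabeculae=int(r.n_trabeculae),
            measured_concentration=(str(r.measured_concentration).lower() == "yes"),
        ))
    return tuple(rows)


def _load_table3() -> dict[tuple[str, str], DrugEntry]:
    import io

    df = pd.read_csv(io.BytesIO(_read_packaged("table3.csv")))
    params: dict[tuple[str, str, str], HillParameters] = {}
    for r in df.itertuples():
        if pd.notna(r.censored_above_um):
            hp = HillParameters(ic50=None, h=None, censored_above=float(r.censored_above_um))
        else:
            hp = HillParameters(ic50=float(r.ic50_um), h=float(r.hill))
        params[(r.drug, r.dataset, r.channel)] = hp
    out: dict[tuple[str, str], DrugEntry] = {}
    for (drug, dataset, _), _hp in params.items():
        key = (drug, dataset)
        if key in out:
            continue
        out[key] = DrugEntry(
            drug=drug, dataset=dataset,
            ikr=params[(drug, dataset, "IKr")],
            ical=params[(drug, dataset, "ICaL")],
        )
    return out


def _load_table4() -> tuple[RosterRow, ...]:
    import io

    df = pd.read_csv(io.BytesIO(_read_packaged("table4.csv")))
    return tuple(
        RosterRow(
            model=r.model,
            structure=r.structure,
            endocardial_selected=(str(r.endocardial_selected).lower() == "yes"),
            tier=r.tier,
            gks_ms_per_uf=float(r.gks_ms_per_uf) if pd.notna(r.gks_ms_per_uf) else None,
            reference=r.reference,
        )
        for r in df.itertuples()
    )


def _validate(tables: StudyTables) -> None:
    conds = tables.conditions
    if len(set(conds)) != len(conds):
        raise TableValidationError("duplicate (drug, concentration) rows in table 1")
    if len(conds) != 29:
        raise TableValidationError(
            f"expected 29 unique drug-concentration conditions, found {len(conds)}"
        )
    panel_conc = {}
    for row in tables.table2:
        panel_conc.setdefault(row.drug, set()).update(row.concentrations)
    for drug, conc in conds:
        if drug not in panel_conc or conc not in panel_conc[drug]:
            raise TableValidationError(
                f"table-1 condition ({drug}, {conc}) missing from the table-2 panel"
            )
    for drug in panel_conc:
        for ds in ("CiPA", "Pharm"):
            if (drug, ds) not in tables.table3:
                raise TableValidationError(
                    f"drug {drug} lacks table-3 Hill parameters in dataset {ds}"
                )
    # censoring must agree across datasets (selectivity is a drug property here)
    for drug in panel_conc:
        cipa, pharm = tables.table3[(drug, "CiPA")], tables.table3[(drug, "Pharm")]
        if cipa.ikr.censored != pharm.ikr.censored or cipa.ical.censored != pharm.ical.censored:
            raise TableValidationError(f"censoring disagrees across datasets for {drug}")


_CACHE: StudyTables | None = None


def load_study_tables(validate: bool = True, path=None) -> StudyTables:
    """Load and validate the study tables.

    By default the packaged, checksummed resources are read; ``path`` may
    point at a directory holding the same CSV schemas (e.g. written by
    :func:`write_study_tables`, or a synthetic drop-in study), in which
    case no checksum is enforced.
    """
    global _CACHE, _SOURCE_DIR
    if path is None and _CACHE is not None:
        return _CACHE
    _SOURCE_DIR = Path(path) if path is not None else None
    try:
        if path is None:
            _check_checksums()
        tables = StudyTables(
            table1=_load_table1(),
            table2=_load_table2(),
            table3=_load_table3(),
            table4=_load_table4(),
        )
    finally:
        _SOURCE_DIR = None
    if validate:
        _validate(tables)
    if path is None:
        _CACHE = tables
    return tables


def write_study_tables(tables: StudyTables, path) -> list[Path]:
    """Write the typed tables back out in the packaged CSV schemas."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    rows1 = [{"drug": r.drug, "concentration_um": r.concentration,
              "mean_delta_apd90_ms": r.mean_delta_apd90, "sem_ms": r.sem,
              "baseline_apd90_ms": r.mean_baseline_apd90,
              "baseline_sd_ms": r.baseline_sd} for r in tables.table1]
    f = out / "table1.csv"
    pd.DataFrame(rows1).to_csv(f, index=False)
    written.append(f)

    rows2 = []
    for r in tables.table2:
        concs = list(r.concentrations) + [None] * (4 - len(r.concentrations))
        rows2.append({"drug": r.drug, "conc1_um": concs[0], "conc2_um": concs[1],
                      "conc3_um": concs[2], "conc4_um": concs[3],
                      "n_trabeculae": r.n_trabeculae,
                      "measured_concentration": "yes" if r.measured_concentration else "no"})
    f = out / "table2.csv"
    pd.DataFrame(rows2).to_csv(f, index=False)
    written.append(f)

    rows3 = []
    for (drug, dataset), entry in sorted(tables.table3.items()):
        for channel, hp in (("ICaL", entry.ical), ("IKr", entry.ikr)):
            rows3.append({"drug": drug, "dataset": dataset, "channel": channel,
                          "ic50_um": hp.ic50, "hill": hp.h,
                          "censored_above_um": hp.censored_above})
    f = out / "table3.csv"
    pd.DataFrame(rows3).to_csv(f, index=False)
    written.append(f)

    rows4 = [{"model": r.model, "structure": r.structure,
              "endocardial_selected": "yes" if r.endocardial_selected else "no",
              "tier": r.tier, "gks_ms_per_uf": r.gks_ms_per_uf,
              "reference": r.reference} for r in tables.table4]
    f = out / "table4.csv"
    pd.DataFrame(rows4).to_csv(f, index=False)
    written.append(f)
    return written


# ---------------------------------------------------------------------------
# report bundle


def write_report_bundle(results: Mapping, path) -> list[Path]:
    """Write a deterministic file bundle of benchmark results.

    ``results`` may contain (all optional):

    - ``"maps"``: list of :class:`DeltaAPDMap`;
    - ``"errors"``: mapping (model, dataset) -> :class:`ErrorReport`;
    - ``"surfaces"``: mapping dataset -> :class:`SurfaceFit`;
    - ``"config"``: a JSON-serialisable run configuration.

    Content files are byte-stable for identical inputs; the run manifest
    alone carries the timestamp.
    """
    import datetime

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for map_ in results.get("maps", []):
        name = f"map_{map_.model}_{map_.concentration_mode}.csv"
        f = out / name
        map_.to_frame().to_csv(f, float_format="%.6g")
        written.append(f)

    for (model, dataset), report in sorted(results.get("errors", {}).items()):
        f = out / f"error_{model}_{dataset}.csv"
        report.to_frame().to_csv(f, index=False, float_format="%.6g")
        written.append(f)
        fj = out / f"error_{model}_{dataset}.json"
        fj.write_text(json.dumps(
            {"model": model, "dataset": dataset, "total_e": report.total_e,
             "per_drug": dict(sorted(report.per_drug.items()))},
            indent=2, sort_keys=True) + "\n")
        written.append(fj)

    for dataset, fit in sorted(results.get("surfaces", {}).items()):
        f = out / f"surface_{dataset}.json"
        f.write_text(json.dumps(
            {"dataset": dataset,
             "exponents": [[i, j] for i, j in CUBIC_EXPONENTS],
             "coefficients": [float(c) for c in fit.coefficients]},
            indent=2) + "\n")
        written.append(f)

    config = results.get("config", {})
    config_text = json.dumps(config, indent=2, sort_keys=True)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "files": sorted(f.name for f in written),
        "package": "apdbench",
        "written_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    mf = out / "manifest.json"
    mf.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mf)
    return written
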