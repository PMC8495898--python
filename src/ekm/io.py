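"""Readers and writers for branching tables, ladders, configs, and results.

File formats
------------
* Branching table: CSV/TSV with header
  ``analyte,reference,e_lab_eV,e_cm_eV,i_analyte,i_reference,replicate``;
  exactly one of ``e_lab_eV``/``e_cm_eV`` may be empty per row; comment
  lines start with ``#``.
* Reference ladder: CSV with header
  ``name,dH_kJmol,dH_unc_kJmol,dS_JmolK,dS_unc_JmolK,GA_kJmol``.
* Config: TOML or YAML with keys ``m_gas_Da``, ``dimer_mass_Da`` (map keyed
  ``analyte|reference``), ``site_label``, ``temperature_K``.
* Results: JSON, round-tripping all numeric fields bit-for-bit (floats are
  serialized at full repr precision).
"""

from __future__ import annotations

import hashlib
import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

from .core import EKMResult, ReferenceAcid, SchemaError, T_STD
from .kinetics import ECM_GROUP_TOL, center_of_mass_energy

__all__ = [
    "BranchingMeasurement",
    "CIDDataset",
    "read_reference_ladder",
    "read_branching_table",
    "write_branching_table",
    "read_config",
    "write_result",
    "read_result",
]

BRANCHING_COLUMNS = [
    "analyte",
    "reference",
    "e_lab_eV",
    "e_cm_eV",
    "i_analyte",
    "i_reference",
    "replicate",
]
LADDER_COLUMNS = [
    "name",
    "dH_kJmol",
    "dH_unc_kJmol",
    "dS_JmolK",
    "dS_unc_JmolK",
    "GA_kJmol",
]


@dataclass(frozen=True)
class BranchingMeasurement:
    """One CID acquisition of a mass-selected heterodimer.

    Intensities are the fragment-ion abundances of the two competing
    dissociation channels (arbitrary counts); both must be positive —
    zero-count channels are rejected before any ratio is taken.
    """

    analyte: str
    reference: str
    i_analyte: float
    i_reference: float
    e_cm: float | None = None
    e_lab: float | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.i_analyte <= 0 or self.i_reference <= 0:
            raise ValueError(
                f"intensities must be positive, got "
                f"({self.i_analyte}, {self.i_reference})"
            )
        if self.e_cm is None and self.e_lab is None:
            raise ValueError("at least one of e_cm, e_lab must be given")


@dataclass
class CIDDataset:
    """A set of branching measurements for one analyte/site.

    ``dimer_mass`` maps reference name → heterodimer ion mass (Da) and,
    with ``m_gas``, supports the lab→CM energy conversion.  Every reference
    must appear at ≥ 3 distinct collision energies: the second-stage
    regression needs T_eff spread.
    """

    measurements: list[BranchingMeasurement]
    m_gas: float | None = None
    dimer_mass: Mapping[str, float] | None = None
    site_label: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError("dataset has no measurements")
        if self.m_gas is not None and self.m_gas <= 0:
            raise ValueError("collision-gas mass must be positive")
        if self.m_gas is not None and self.dimer_mass is not None:
            for name, M in self.dimer_mass.items():
                if M <= self.m_gas:
                    raise ValueError(
                        f"dimer mass for {name} ({M} Da) must exceed the "
                        f"collision-gas mass ({self.m_gas} Da)"
                    )
        by_ref: dict[str, set[float]] = {}
        for m in self.measurements:
            if m.e_cm is not None:
                key = round(m.e_cm / ECM_GROUP_TOL)
                by_ref.setdefault(m.reference, set()).add(key)
        thin = sorted(r for r, ks in by_ref.items() if len(ks) < 3)
        if thin:
            raise ValueError(
                f"references with fewer than 3 distinct collision energies: "
                f"{', '.join(thin)}"
            )

    @property
    def e_cm_groups(self) -> list[float]:
        """Sorted distinct center-of-mass energies (grouped within tolerance)."""
        seen: dict[int, float] = {}
        for m in self.measurements:
            if m.e_cm is not None:
                seen.setdefault(round(m.e_cm / ECM_GROUP_TOL), m.e_cm)
        return sorted(seen.values())

    @property
    def references(self) -> list[str]:
        return sorted({m.reference for m in self.measurements})


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(
            path,
            sep=sep,
            comment="#",
            skip_blank_lines=True,
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_reference_ladder(path: str | Path) -> list[ReferenceAcid]:
    """Read an acidity ladder from delimited text."""
    df = _read_table(path, LADDER_COLUMNS[:5])  # GA column optional
    refs = []
    for _, row in df.iterrows():
        ga = row.get("GA_kJmol")
        refs.append(
            ReferenceAcid(
                name=str(row["name"]),
                dH=float(row["dH_kJmol"]),
                dH_unc=float(row["dH_unc_kJmol"]),
                dS=float(row["dS_JmolK"]),
                dS_unc=float(row["dS_unc_JmolK"]),
                ga=None if ga is None or (isinstance(ga, float) and math.isnan(ga)) else float(ga),
            )
        )
    return refs


def read_branching_table(
    path: str | Path,
    config: Mapping[str, Any] | None = None,
    ladder: Iterable[ReferenceAcid] | None = None,
) -> CIDDataset:
    """Read and validate a CID branching-ratio table.

    Rows with non-positive intensities are rejected with their (1-based,
    header-exclusive) row numbers reported.  When ``e_cm_eV`` is empty the
    center-of-mass energy is computed from ``e_lab_eV`` using the masses in
    ``config`` (``m_gas_Da`` and the per-pair ``dimer_mass_Da`` map).  When
    a ladder is supplied, unknown reference names raise a cross-reference
    error.
    """
    df = _read_table(path, BRANCHING_COLUMNS)
    config = dict(config or {})
    m_gas = config.get("m_gas_Da")
    dimer_map = dict(config.get("dimer_mass_Da", {}))

    bad = [
        int(i) + 1
        for i, (ia, ir) in enumerate(zip(df["i_analyte"], df["i_reference"]))
        if not (ia > 0 and ir > 0)
    ]
    if bad:
        raise SchemaError(
            f"{path}: non-positive intensities in data row(s) {bad}"
        )

    if ladder is not None:
        known = {r.name for r in ladder}
        unknown = sorted(set(df["reference"].astype(str)) - known)
        if unknown:
            raise SchemaError(
                f"{path}: reference name(s) not in ladder: {', '.join(unknown)}"
            )

    measurements = []
    for i, row in df.iterrows():
        e_lab = row["e_lab_eV"]
        e_cm = row["e_cm_eV"]
        e_lab = None if pd.isna(e_lab) else float(e_lab)
        e_cm = None if pd.isna(e_cm) else float(e_cm)
        if e_cm is None:
            if e_lab is None:
                raise SchemaError(
                    f"{path}: data row {int(i) + 1} has neither e_lab_eV nor e_cm_eV"
                )
            pair = f"{row['analyte']}|{row['reference']}"
            if m_gas is None or pair not in dimer_map:
                raise SchemaError(
                    f"{path}: data row {int(i) + 1} needs m_gas_Da and "
                    f"dimer_mass_Da['{pair}'] in the config to convert e_lab"
                )
            e_cm = center_of_mass_energy(e_lab, float(m_gas), float(dimer_map[pair]))
        measurements.append(
            BranchingMeasurement(
                analyte=str(row["analyte"]),
                reference=str(row["reference"]),
                i_analyte=float(row["i_analyte"]),
                i_reference=float(row["i_reference"]),
                e_cm=e_cm,
                e_lab=e_lab,
                replicate=int(row["replicate"]),
            )
        )
    dimer_by_ref = {
        pair.split("|", 1)[1]: float(M) for pair, M in dimer_map.items()
    }
    return CIDDataset(
        measurements=measurements,
        m_gas=float(m_gas) if m_gas is not None else None,
        dimer_mass=dimer_by_ref or None,
        site_label=str(config.get("site_label", "")),
        metadata={"source": str(path), "replicate_averaging": "mean of ln-ratios"},
    )


def write_branching_table(dataset: CIDDataset, path: str | Path) -> None:
    """Write a dataset back to the canonical CSV schema."""
    rows = [
        {
            "analyte": m.analyte,
            "reference": m.reference,
            "e_lab_eV": "" if m.e_lab is None else repr(m.e_lab),
            "e_cm_eV": "" if m.e_cm is None else repr(m.e_cm),
            "i_analyte": repr(m.i_analyte),
            "i_reference": repr(m.i_reference),
            "replicate": m.replicate,
        }
        for m in dataset.measurements
    ]
    pd.DataFrame(rows, columns=BRANCHING_COLUMNS).to_csv(path, index=False)


def read_config(path: str | Path) -> dict[str, Any]:
    """Read a TOML (.toml) or YAML (.yml/.yaml) configuration file."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path) as fh:
            out = yaml.safe_load(fh)
            if not isinstance(out, dict):
                raise SchemaError(f"{path}: config must be a mapping")
            return out
    raise SchemaError(f"{path}: unsupported config format (use .toml/.yaml)")


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for provenance manifests."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_result(
    result: EKMResult,
    path: str | Path,
    manifest: Mapping[str, Any] | None = None,
) -> None:
    """Serialize an :class:`EKMResult` to JSON.

    The document carries units, the constants used, the uncertainty
    convention, the package version, and an optional run manifest; numeric
    fields survive a read/write round trip bit-for-bit.
    """
    from . import __version__

    doc = {
        "schema": "ekm-result/1",
        "package_version": __version__,
        "site_label": result.site_label,
        "values": {
            "dH_kJmol": result.dH,
            "dH_unc_kJmol": result.dH_unc,
            "dS_JmolK": result.dS,
            "dS_unc_JmolK": result.dS_unc,
            "GA_kJmol": result.ga,
            "GA_unc_kJmol": result.ga_unc,
            "ddS_JmolK": result.ddS,
        },
        "units": {
            "dH": "kJ/mol",
            "dS": "J/(mol K)",
            "GA": "kJ/mol",
            "ddS": "J/(mol K)",
        },
        "constants": {"R_J_per_molK": 8.3145, "temperature_K": result.temperature},
        "uncertainty_convention": "1-sigma standard uncertainty, ingested as-is",
        "manifest": dict(manifest or {}),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_result(path: str | Path) -> EKMResult:
    """Load an :class:`EKMResult` previously written by :func:`write_result`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != "ekm-result/1":
        raise SchemaError(f"{path}: not an ekm-result/1 document")
    v = doc["values"]
    return EKMResult(
        dH=v["dH_kJmol"],
        dH_unc=v["dH_unc_kJmol"],
        dS=v["dS_JmolK"],
        dS_unc=v["dS_unc_JmolK"],
        ga=v["GA_kJmol"],
        ga_unc=v["GA_unc_kJmol"],
        ddS=v["ddS_JmolK"],
        site_label=doc.get("site_label", ""),
        temperature=doc["constants"].get("temperature_K", T_STD),
    )
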