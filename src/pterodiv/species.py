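"""Species-table ingestion, validation and summaries.

The species table mirrors the published checklist of the genus: one row per
species with a previous name (if the species was split out in the revision),
availability flags for molecular and morphological data, the occupied
biogeographic areas as concatenated letters (subset of A-I), and the mean
plus 95%-interval boundaries of the species' elevational records in metres.
A transcription of that checklist ships with the package as a fixture,
guarded by a checksum against accidental edits.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .biogeo import DEFAULT_AREAS, AreaSystem

__all__ = [
    "SpeciesRecord",
    "CalibrationPrior",
    "SpeciesTableError",
    "load_species_table",
    "packaged_species_table",
    "area_richness",
    "build_calibration_priors",
    "records_to_frame",
]

EXPECTED_COLUMNS = [
    "species", "previous_name", "molecular", "morphology",
    "areas", "elev_mean", "elev_low", "elev_high",
]

# sha256 of the packaged checklist fixture; guards accidental edits
_FIXTURE_SHA256_EXPECTED = "2306ce25241b55f3e8d3ac48222d483745f2299a346bd6253fe6b15669399151"


class SpeciesTableError(ValueError):
    """Validation failure, addressed to a specific row where possible."""


@dataclass
class SpeciesRecord:
    species: str
    previous_name: str
    molecular: bool
    morphology: bool
    areas: str  # concatenated letters, e.g. "ACDE"
    elev_mean: float  # m
    elev_low: float
    elev_high: float


@dataclass
class CalibrationPrior:
    clade: str
    kind: str  # always "uniform" for host-plant maxima
    lower: float  # my; 0 for host-plant priors
    upper: float  # my

    def as_dict(self) -> dict:
        return {"clade": self.clade, "kind": self.kind,
                "lower_my": self.lower, "upper_my": self.upper}


def _truthy(x) -> bool:
    if pd.isna(x):
        return False
    return str(x).strip().lower() in ("x", "1", "true", "yes")


def load_species_table(source, areas: AreaSystem = DEFAULT_AREAS,
                       strict: bool = True) -> list[SpeciesRecord]:
    """Read and validate the species CSV.

    Errors carry the 1-based data row number. In strict mode missing
    elevations are refused; otherwise such species are kept but flagged by
    NaN elevations (downstream trait stages drop them).
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False, na_values=[""])
    missing_cols = [c for c in EXPECTED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SpeciesTableError(f"missing columns: {', '.join(missing_cols)}")
    records: list[SpeciesRecord] = []
    seen: dict[str, int] = {}
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        name = str(row["species"]).strip()
        if not name or pd.isna(row["species"]):
            raise SpeciesTableError(f"empty species name at row {pos}")
        if name in seen:
            raise SpeciesTableError(
                f"duplicate species {name!r} at row {pos} (first at row {seen[name]})"
            )
        seen[name] = pos
        area_str = "" if pd.isna(row["areas"]) else str(row["areas"]).strip()
        if not area_str:
            raise SpeciesTableError(f"empty area string at row {pos}")
        for ch in area_str:
            if ch not in areas.labels:
                raise SpeciesTableError(f"unknown area {ch} at row {pos}")
        if len(set(area_str)) != len(area_str):
            raise SpeciesTableError(f"duplicate area letter at row {pos}")
        elev = {}
        for col in ("elev_mean", "elev_low", "elev_high"):
            val = row[col]
            if pd.isna(val):
                if strict:
                    raise SpeciesTableError(f"missing {col} at row {pos}")
                elev[col] = float("nan")
                continue
            try:
                elev[col] = float(val)
            except ValueError:
                raise SpeciesTableError(
                    f"non-numeric {col} {val!r} at row {pos}"
                ) from None
        if all(v == v for v in elev.values()):  # no NaNs
            if not elev["elev_low"] <= elev["elev_mean"] <= elev["elev_high"]:
                raise SpeciesTableError(
                    f"elevational ordering violated at row {pos}: "
                    f"{elev['elev_low']} <= {elev['elev_mean']} <= "
                    f"{elev['elev_high']} fails"
                )
        records.append(SpeciesRecord(
            species=name,
            previous_name="" if pd.isna(row["previous_name"])
            else str(row["previous_name"]).strip(),
            molecular=_truthy(row["molecular"]),
            morphology=_truthy(row["morphology"]),
            areas=area_str,
            elev_mean=elev["elev_mean"],
            elev_low=elev["elev_low"],
            elev_high=elev["elev_high"],
        ))
    return records


def packaged_species_table(verify_checksum: bool = True) -> list[SpeciesRecord]:
    """The transcribed checklist fixture shipped with the package."""
    ref = resources.files("pterodiv") / "data" / "species_checklist.csv"
    raw = ref.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _FIXTURE_SHA256_EXPECTED:
            raise SpeciesTableError(
                "packaged species table was modified: checksum mismatch "
                f"({digest[:12]}... != {_FIXTURE_SHA256_EXPECTED[:12]}...)"
            )
    import io

    return load_species_table(io.BytesIO(raw))


def area_richness(records: list[SpeciesRecord],
                  areas: AreaSystem = DEFAULT_AREAS) -> dict[str, int]:
    """Species count per area; multi-area species count once per area."""
    counts = {a: 0 for a in areas.labels}
    for rec in records:
        for ch in rec.areas:
            counts[ch] += 1
    return counts


def build_calibration_priors(host_plant_ages) -> list[CalibrationPrior]:
    """Uniform(0, CI upper bound) calibration priors from host-plant ages.

    Each entry is (clade label, median age my, ci_low, ci_high); the prior's
    upper bound is the upper boundary of the 95% credibility interval of the
    host-plant lineage age and the lower bound is the present.
    """
    priors = []
    for entry in host_plant_ages:
        label, median, ci_low, ci_high = entry
        if ci_low is None or ci_high is None:
            raise ValueError(f"{label}: missing credibility interval")
        if not ci_low <= median <= ci_high:
            raise ValueError(
                f"{label}: CI [{ci_low}, {ci_high}] does not bracket "
                f"median {median}"
            )
        priors.append(CalibrationPrior(
            clade=str(label), kind="uniform", lower=0.0, upper=float(ci_high)
        ))
    return priors


def records_to_frame(records: list[SpeciesRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "species": r.species,
        "previous_name": r.previous_name,
        "molecular": "x" if r.molecular else "",
        "morphology": "x" if r.morphology else "",
        "areas": r.areas,
        "elev_mean": r.elev_mean,
        "elev_low": r.elev_low,
        "elev_high": r.elev_high,
    } for r in records])


def write_species_table(records: list[SpeciesRecord], path: Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
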