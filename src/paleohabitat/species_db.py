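"""Parsing, filtering and scenario resolution of the hominin species database.

The species database (SDB) is a table of dated, located fossil and
archaeological occurrences, each attributed to one or more of five hominin
groups: early African *Homo* (the merged *H. habilis* / *H. ergaster*
Oldowan toolmakers), Eurasian *H. erectus*, *H. heidelbergensis*,
*H. neanderthalensis* and *H. sapiens*.  Entries with a single confident
attribution form the *core* record; entries listing several candidate
species form the *extended* record.  Four scenarios resolve attribution
and dating-multiplicity uncertainty:

==============  ======================================================
multiple/tier1  core record only, every dated entry kept
multiple/tier2  extended record, ambiguous attributions drawn at random
single/tier1    core record, one combined entry per archaeological layer
single/tier2    extended record, one combined entry per layer
==============  ======================================================

In the *single* modes the age estimates of a layer are combined into the
envelope ``[min(t - Δt), max(t + Δt)]``; the layer's entry carries the
midpoint as its age and half the span as its uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = (
    "early_african_homo",
    "erectus",
    "heidelbergensis",
    "neanderthalensis",
    "sapiens",
)

#: raw labels before the habilis/ergaster merge
RAW_SPECIES = ("habilis", "ergaster") + SPECIES[1:]

#: default canonicalization of raw spellings (lower-cased, stripped of
#: "homo"/"h." prefixes) to raw species labels; shipped as data so users
#: can extend it for their own spreadsheets
CANONICAL_NAMES: dict[str, str] = {
    "habilis": "habilis",
    "ergaster": "ergaster",
    "early african homo": "early_african_homo",
    "early_african_homo": "early_african_homo",
    "erectus": "erectus",
    "heidelbergensis": "heidelbergensis",
    "neanderthalensis": "neanderthalensis",
    "neandertal": "neanderthalensis",
    "neanderthal": "neanderthalensis",
    "sapiens": "sapiens",
}

DEFAULT_COLUMNS: dict[str, str] = {
    "site_name": "site_name",
    "layer_id": "layer_id",
    "lon": "lon",
    "lat": "lat",
    "age_ka": "age_ka",
    "age_uncertainty_ka": "age_uncertainty_ka",
    "species": "species",
    "dating_method": "dating_method",
    "region": "region",
}

MANDATORY = ("site_name", "lon", "lat", "age_ka", "species")

AGE_WINDOW_KA = (30.0, 2000.0)  # analysis window: 2 Ma to 30 ka

# fallback bounding boxes when no region column is available
AMERICAS_LON = (-170.0, -30.0)
AUSTRALIA_LON = (110.0, 155.0)
AUSTRALIA_LAT = (-45.0, -10.0)


@dataclass(frozen=True)
class FossilRecord:
    """One dated, located, species-attributed occurrence."""

    site_name: str
    layer_id: str
    lon: float
    lat: float
    age_ka: float
    age_uncertainty_ka: float
    attributions: tuple[str, ...]
    dating_method: str = ""
    region: str = ""

    @property
    def is_core(self) -> bool:
        """Single, unambiguous species attribution."""
        return len(self.attributions) == 1


@dataclass(frozen=True)
class ScenarioConfig:
    """One of the four attribution/dating scenarios."""

    date_mode: str  # "multiple" | "single"
    tier: int  # 1 (core record) | 2 (extended record)
    seed: int | None = None  # required for tier 2 (random attribution)

    def __post_init__(self) -> None:
        if self.date_mode not in ("multiple", "single"):
            raise ValueError("date_mode must be 'multiple' or 'single'")
        if self.tier not in (1, 2):
            raise ValueError("tier must be 1 or 2")


@dataclass
class ScenarioRecords:
    """Scenario-resolved records, one species attribution each."""

    by_species: dict[str, list[FossilRecord]]
    provenance: ScenarioConfig

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.by_species.values())

    def records(self) -> list[FossilRecord]:
        return [r for recs in self.by_species.values() for r in recs]


@dataclass
class ParseResult:
    records: list[FossilRecord]
    rejects: pd.DataFrame  # offending rows with a 'reject_reason' column


def canonical_species(raw: str, table: dict[str, str] | None = None) -> str:
    """Map a raw spelling ('H. habilis', 'Homo sapiens', ...) to its label."""
    table = CANONICAL_NAMES if table is None else table
    key = raw.strip().lower().replace("_", " ")
    for prefix in ("homo ", "h. ", "h "):
        if key.startswith(prefix):
            key = key[len(prefix):]
    key = key.strip()
    if key in table:
        return table[key]
    raise ValueError(f"unknown species spelling: {raw!r}")


def _split_attributions(cell: str) -> list[str]:
    for sep in (";", "|", "/"):
        if sep in cell:
            return [p for p in (s.strip() for s in cell.split(sep)) if p]
    return [cell.strip()]


def parse_sdb(
    path,
    column_map: dict[str, str] | None = None,
    delimiter: str | None = None,
    name_table: dict[str, str] | None = None,
) -> ParseResult:
    """Read a delimited SDB table into records plus a rejects report.

    Rows with malformed coordinates, non-positive ages, negative age
    uncertainties or unknown species spellings are routed into
    ``rejects`` (with a reason) rather than silently dropped.  A blank
    age uncertainty defaults to 0 with a logged warning.  A missing
    mandatory column raises, naming the column.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str, keep_default_na=False)
    for logical in MANDATORY:
        if cols[logical] not in df.columns:
            raise ValueError(f"mandatory column {cols[logical]!r} ({logical}) missing")

    records: list[FossilRecord] = []
    reject_rows: list[dict] = []

    def _get(row, logical, default=""):
        col = cols[logical]
        return row[col] if col in df.columns else default

    n_blank_dt = 0
    for idx, row in df.iterrows():
        reason = None
        try:
            lon = float(_get(row, "lon"))
            lat = float(_get(row, "lat"))
            age = float(_get(row, "age_ka"))
            dt_raw = str(_get(row, "age_uncertainty_ka")).strip()
            if dt_raw == "":
                dt = 0.0
                n_blank_dt += 1
            else:
                dt = float(dt_raw)
            attributions = tuple(
                canonical_species(s, name_table) for s in _split_attributions(str(_get(row, "species")))
            )
        except (ValueError, TypeError) as exc:
            reason = str(exc)
        else:
            if not attributions:
                reason = "no species attribution"
            elif abs(lat) > 90:
                reason = f"latitude {lat} outside [-90, 90]"
            elif not (-180 <= lon < 360):
                reason = f"longitude {lon} outside [-180, 360)"
            elif age <= 0:
                reason = f"non-positive age {age}"
            elif dt < 0:
                reason = f"negative age uncertainty {dt}"
        if reason is not None:
            rec = row.to_dict()
            rec["reject_reason"] = reason
            rec["row_index"] = idx
            reject_rows.append(rec)
            continue
        records.append(
            FossilRecord(
                site_name=str(_get(row, "site_name")).strip(),
                layer_id=str(_get(row, "layer_id")).strip(),
                lon=lon,
                lat=lat,
                age_ka=age,
                age_uncertainty_ka=dt,
                attributions=attributions,
                dating_method=str(_get(row, "dating_method")).strip(),
                region=str(_get(row, "region")).strip(),
            )
        )
    if n_blank_dt:
        logger.warning("%d rows had blank age uncertainty; defaulted to 0", n_blank_dt)
    rejects = pd.DataFrame(reject_rows)
    return ParseResult(records=records, rejects=rejects)


def _excluded_region(r: FossilRecord) -> bool:
    region = r.region.strip().lower()
    if region:
        return region in ("americas", "america", "australia")
    if AMERICAS_LON[0] <= r.lon <= AMERICAS_LON[1]:
        return True
    if AUSTRALIA_LON[0] <= r.lon <= AUSTRALIA_LON[1] and AUSTRALIA_LAT[0] <= r.lat <= AUSTRALIA_LAT[1]:
        return True
    return False


def filter_records(records: list[FossilRecord]) -> list[FossilRecord]:
    """Apply the analysis-window and region filters and the species merge.

    Keeps ages in [30, 2000] ka, drops Australia/Americas occurrences
    (region column when present, bounding boxes otherwise) and rewrites
    *habilis*/*ergaster* attributions to ``early_african_homo``.
    """
    out: list[FossilRecord] = []
    lo, hi = AGE_WINDOW_KA
    for r in records:
        if not (lo <= r.age_ka <= hi):
            continue
        if _excluded_region(r):
            continue
        merged = tuple(
            dict.fromkeys(  # stable-unique: habilis+ergaster collapse to one
                "early_african_homo" if a in ("habilis", "ergaster") else a
                for a in r.attributions
            )
        )
        out.append(replace(r, attributions=merged))
    return out


def _resolve_tier(
    records: list[FossilRecord], tier: int, rng: np.random.Generator | None
) -> list[FossilRecord]:
    """Tier 1: keep core entries only; tier 2: random choice among candidates."""
    resolved: list[FossilRecord] = []
    for r in records:
        if r.is_core:
            resolved.append(r)
        elif tier == 2:
            assert rng is not None
            choice = r.attributions[int(rng.integers(len(r.attributions)))]
            resolved.append(replace(r, attributions=(choice,)))
        # tier 1: ambiguous entry dropped
    return resolved


def _collapse_layers(records: list[FossilRecord]) -> list[FossilRecord]:
    """One entry per (site, layer, species): age envelope over the layer's
    dated entries, midpoint age, half-span uncertainty."""
    groups: dict[tuple[str, str, str], list[FossilRecord]] = {}
    for r in records:
        groups.setdefault((r.site_name, r.layer_id, r.attributions[0]), []).append(r)
    out = []
    for (site, layer, species), recs in groups.items():
        lo = min(r.age_ka - r.age_uncertainty_ka for r in recs)
        hi = max(r.age_ka + r.age_uncertainty_ka for r in recs)
        base = recs[0]
        out.append(
            replace(
                base,
                age_ka=0.5 * (lo + hi),
                age_uncertainty_ka=0.5 * (hi - lo),
            )
        )
    return out


def build_scenario(records: list[FossilRecord], config: ScenarioConfig) -> ScenarioRecords:
    """Resolve filtered records under one of the four scenarios."""
    if config.tier == 2 and config.seed is None:
        raise ValueError("tier-2 scenarios require a seed (random attribution must be reproducible)")
    rng = np.random.default_rng(config.seed) if config.tier == 2 else None
    resolved = _resolve_tier(records, config.tier, rng)
    if config.date_mode == "single":
        resolved = _collapse_layers(resolved)
    by_species: dict[str, list[FossilRecord]] = {s: [] for s in SPECIES}
    for r in resolved:
        by_species.setdefault(r.attributions[0], []).append(r)
    return ScenarioRecords(by_species=by_species, provenance=config)


def sample_ages(
    record: FossilRecord,
    n_draws: int,
    rng: np.random.Generator,
    distribution: str = "uniform",
) -> np.ndarray:
    """Monte-Carlo draws from a record's age distribution (ka, all > 0).

    ``uniform``: uniform on [t - Δt, t + Δt] (assumption-minimal for a
    half-width uncertainty).  ``truncnorm``: normal with sd = Δt/2
    truncated to the same interval.  The interval is floored at a small
    positive age.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    t, dt = record.age_ka, record.age_uncertainty_ka
    if dt == 0:
        return np.full(n_draws, t)
    lo = max(t - dt, 1e-6)
    hi = t + dt
    if distribution == "uniform":
        return rng.uniform(lo, hi, size=n_draws)
    if distribution == "truncnorm":
        sd = dt / 2
        a, b = (lo - t) / sd, (hi - t) / sd
        from scipy import stats

        return stats.truncnorm.rvs(a, b, loc=t, scale=sd, size=n_draws, random_state=rng)
    raise ValueError(f"unknown age distribution {distribution!r}")


def summarize(scenario: ScenarioRecords) -> dict:
    """Totals, per-species counts and fractions for a resolved scenario."""
    counts = {s: len(v) for s, v in scenario.by_species.items()}
    total = sum(counts.values())
    fractions = {s: (c / total if total else 0.0) for s, c in counts.items()}
    return {
        "date_mode": scenario.provenance.date_mode,
        "tier": scenario.provenance.tier,
        "total": total,
        "counts": counts,
        "fractions": fractions,
    }


def records_to_frame(records: list[FossilRecord]) -> pd.DataFrame:
    """Flatten records to the CSV schema (attributions ';'-joined)."""
    return pd.DataFrame(
        {
            "site_name": [r.site_name for r in records],
            "layer_id": [r.layer_id for r in records],
            "lon": [r.lon for r in records],
            "lat": [r.lat for r in records],
            "age_ka": [r.age_ka for r in records],
            "age_uncertainty_ka": [r.age_uncertainty_ka for r in records],
            "species": [";".join(r.attributions) for r in records],
            "dating_method": [r.dating_method for r in records],
            "region": [r.region for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame) -> list[FossilRecord]:
    """Inverse of :func:`records_to_frame` for already-canonical tables."""
    out = []
    for _, row in df.iterrows():
        out.append(
            FossilRecord(
                site_name=str(row["site_name"]),
                layer_id=str(row.get("layer_id", "") or ""),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                age_ka=float(row["age_ka"]),
                age_uncertainty_ka=float(row.get("age_uncertainty_ka", 0.0)),
                attributions=tuple(str(row["species"]).split(";")),
                dating_method=str(row.get("dating_method", "") or ""),
                region=str(row.get("region", "") or ""),
            )
        )
    return out
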