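"""Domain types and I/O for repeated-count amphibian survey data.

The core container is :class:`SurveyDataset`: integer counts of egg masses
plus larvae, indexed (species, site, survey), together with the two
survey-level detection covariates used throughout — days elapsed since
1 February and water temperature.  Site-level covariates live in
:class:`SiteTable`.

A 30-site detection/hydrology/fish table from a Middle Danube floodplain
survey is packaged verbatim (:func:`table1_fixture`) and is used by the test
suite to pin down the naive summary statistics (per-species detection
tallies, connectivity and fish-richness means, their correlation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "SurveyDataset",
    "SiteTable",
    "DetectionRecord",
    "read_survey_csv",
    "write_survey_csv",
    "read_site_csv",
    "write_site_csv",
    "table1_fixture",
    "fixture_to_json",
    "detection_site_count",
    "summary_stats",
    "pearson_r",
    "round_half_up",
    "SURVEY_SCHEMA",
]

#: canonical column names of the long ("tidy") survey CSV dialect
SURVEY_SCHEMA: dict[str, str] = {
    "species": "species",
    "site": "site",
    "survey": "survey",
    "count": "count",
    "days": "days",
    "water_temp": "water_temp",
    "dry": "dry",
}


@dataclass
class SurveyDataset:
    """Counts from repeated surveys of a species community at fixed sites.

    Attributes
    ----------
    species_ids, site_ids : list of str
        Ordered labels; array axes follow this order.
    counts : ndarray, shape (n_species, n_sites, n_surveys)
        Non-negative integer counts (egg masses + larvae summed per survey).
    days : ndarray, shape (n_sites, n_surveys)
        Days elapsed since 1 February on each survey.
    water_temp : ndarray, shape (n_sites, n_surveys)
        Water temperature (deg C) on each survey.
    dry_flag : ndarray of bool, shape (n_sites, n_surveys)
        True where the site was dry on that survey; such cells must carry a
        zero count for every species.
    """

    species_ids: list[str]
    site_ids: list[str]
    counts: np.ndarray
    days: np.ndarray
    water_temp: np.ndarray
    dry_flag: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.species_ids = list(self.species_ids)
        self.site_ids = list(self.site_ids)
        self.counts = np.asarray(self.counts)
        self.days = np.asarray(self.days, dtype=float)
        self.water_temp = np.asarray(self.water_temp, dtype=float)
        if self.dry_flag is None:
            self.dry_flag = np.zeros(self.days.shape, dtype=bool)
        self.dry_flag = np.asarray(self.dry_flag, dtype=bool)
        self._validate()

    # -- invariants ---------------------------------------------------------
    def _validate(self) -> None:
        S, J = len(self.species_ids), len(self.site_ids)
        if self.counts.ndim != 3 or self.counts.shape[:2] != (S, J):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{S} species x {J} sites"
            )
        K = self.counts.shape[2]
        for name, arr in (("days", self.days), ("water_temp", self.water_temp),
                          ("dry_flag", self.dry_flag)):
            if arr.shape != (J, K):
                raise ValidationError(f"{name} shape {arr.shape} != {(J, K)}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            frac = self.counts != np.floor(self.counts)
            if np.any(frac):
                idx = np.argwhere(frac)[0]
                raise ValidationError(f"non-integer count at (species,site,survey)={tuple(idx)}")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            idx = np.argwhere(self.counts < 0)[0]
            raise ValidationError(f"negative count at (species,site,survey)={tuple(idx)}")
        if np.any(self.days < 0):
            raise ValidationError("days since 1 February must be >= 0")
        if np.any(self.counts[:, self.dry_flag] != 0):
            raise ValidationError("dry-site surveys must have zero counts for all species")

    # -- convenience --------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_surveys(self) -> int:
        return self.counts.shape[2]

    def reindexed(self, species_ids: Sequence[str], site_ids: Sequence[str]) -> "SurveyDataset":
        """The same data with axes re-ordered to the given id orders
        (content is keyed by ids, so ordering is presentation only)."""
        si = [self.species_ids.index(s) for s in species_ids]
        pj = [self.site_ids.index(s) for s in site_ids]
        return SurveyDataset(
            list(species_ids), list(site_ids),
            self.counts[np.ix_(si, pj)], self.days[pj],
            self.water_temp[pj], self.dry_flag[pj],
        )

    def equals(self, other: "SurveyDataset") -> bool:
        return (
            self.species_ids == other.species_ids
            and self.site_ids == other.site_ids
            and np.array_equal(self.counts, other.counts)
            and np.allclose(self.days, other.days)
            and np.allclose(self.water_temp, other.water_temp)
            and np.array_equal(self.dry_flag, other.dry_flag)
        )


def write_survey_csv(dataset: SurveyDataset, path, schema: Mapping[str, str] | None = None) -> None:
    """Write a dataset in the long CSV dialect (one row per species x site x survey)."""
    cols = dict(SURVEY_SCHEMA, **(schema or {}))
    rows = []
    for i, sp in enumerate(dataset.species_ids):
        for j, site in enumerate(dataset.site_ids):
            for k in range(dataset.n_surveys):
                rows.append({
                    cols["species"]: sp,
                    cols["site"]: site,
                    cols["survey"]: k + 1,
                    cols["count"]: int(dataset.counts[i, j, k]),
                    cols["days"]: dataset.days[j, k],
                    cols["water_temp"]: dataset.water_temp[j, k],
                    cols["dry"]: bool(dataset.dry_flag[j, k]),
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_survey_csv(path, schema: Mapping[str, str] | None = None) -> SurveyDataset:
    """Read a long-format survey CSV into a validated :class:`SurveyDataset`.

    Row order never affects array content: cells are keyed by the
    (species, site, survey) identifiers, with axis order given by first
    appearance in the file.
    """
    cols = dict(SURVEY_SCHEMA, **(schema or {}))
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    counts_raw = df[cols["count"]]
    bad = counts_raw.isna() | (counts_raw != np.floor(counts_raw)) | (counts_raw < 0)
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + 2  # 1-based, counting header
        raise ValidationError(
            f"count must be a non-negative integer (file row {row}: "
            f"{counts_raw.iloc[int(np.argmax(bad.to_numpy()))]!r})"
        )

    species_ids = list(dict.fromkeys(df[cols["species"]].astype(str)))
    site_ids = list(dict.fromkeys(df[cols["site"]].astype(str)))
    surveys = sorted(df[cols["survey"]].unique())
    S, J, K = len(species_ids), len(site_ids), len(surveys)
    sp_idx = {s: i for i, s in enumerate(species_ids)}
    si_idx = {s: j for j, s in enumerate(site_ids)}
    k_idx = {s: k for k, s in enumerate(surveys)}

    counts = np.zeros((S, J, K), dtype=np.int64)
    days = np.full((J, K), np.nan)
    temp = np.full((J, K), np.nan)
    dry = np.zeros((J, K), dtype=bool)
    seen = np.zeros((S, J, K), dtype=bool)
    for _, r in df.iterrows():
        i = sp_idx[str(r[cols["species"]])]
        j = si_idx[str(r[cols["site"]])]
        k = k_idx[r[cols["survey"]]]
        counts[i, j, k] = int(r[cols["count"]])
        days[j, k] = float(r[cols["days"]])
        temp[j, k] = float(r[cols["water_temp"]])
        dry[j, k] = bool(r[cols["dry"]])
        seen[i, j, k] = True
    if not seen.all():
        i, j, k = np.argwhere(~seen)[0]
        raise SchemaError(
            f"incomplete table: no row for species={species_ids[i]!r}, "
            f"site={site_ids[j]!r}, survey={surveys[k]}"
        )
    return SurveyDataset(species_ids, site_ids, counts, days, temp, dry)


# ---------------------------------------------------------------------------
# Site covariate table
# ---------------------------------------------------------------------------

#: raw covariate categories ordinated by PCA downstream
BLOCK_NAMES = ("habitat", "chemistry", "hydrology", "landscape")


@dataclass
class SiteTable:
    """Per-site covariates: hydrology, predatory fish, geometry, raw blocks.

    ``data`` holds one row per site (indexed by site id).  Recognised scalar
    columns: ``hydroperiod`` ('permanent'/'ephemeral'), ``pct_connected``
    (% of days per year connected to the main channel), ``large_fish_richness``,
    ``sampled_area_m2``, ``nn_distance_m``.  ``blocks`` maps a category name
    (habitat / chemistry / hydrology / landscape) to the columns of ``data``
    holding that category's raw variables; missing values (NaN) are allowed
    in the chemistry block only.
    """

    data: pd.DataFrame
    blocks: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("one row per site required (duplicate site ids)")
        d = self.data
        if "pct_connected" in d:
            pc = d["pct_connected"].to_numpy(float)
            if np.any((pc < 0) | (pc > 100)):
                raise ValidationError("pct_connected must lie in [0, 100]")
        if "sampled_area_m2" in d and np.any(d["sampled_area_m2"].to_numpy(float) <= 0):
            raise ValidationError("sampled_area_m2 must be positive")
        if "nn_distance_m" in d and np.any(d["nn_distance_m"].to_numpy(float) <= 0):
            raise ValidationError("nn_distance_m must be positive")
        if "hydroperiod" in d:
            bad = set(d["hydroperiod"]) - {"permanent", "ephemeral"}
            if bad:
                raise ValidationError(f"unknown hydroperiod value(s): {bad}")
        for cat, cols in self.blocks.items():
            missing = [c for c in cols if c not in d.columns]
            if missing:
                raise SchemaError(f"block {cat!r} references absent column(s) {missing}")
            if cat != "chemistry" and d[cols].isna().any().any():
                raise ValidationError(f"missing values only allowed in the chemistry block, not {cat!r}")

    @property
    def site_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def block(self, category: str) -> pd.DataFrame:
        return self.data[self.blocks[category]]


def write_site_csv(table: SiteTable, path) -> None:
    table.data.to_csv(path, index_label="site")


def read_site_csv(path, blocks: Mapping[str, Sequence[str]] | None = None) -> SiteTable:
    df = pd.read_csv(path, index_col="site")
    df.index = df.index.astype(str)
    return SiteTable(df, {k: list(v) for k, v in (blocks or {}).items()})


# ---------------------------------------------------------------------------
# Packaged 30-site detection table (Middle Danube floodplain)
# ---------------------------------------------------------------------------

STAGES = ("egg_mass", "larvae")


@dataclass(frozen=True)
class DetectionRecord:
    """Whether a species' egg masses or larvae were detected at a site."""

    species_id: str
    site_id: str
    stage: str
    detected: bool

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"stage must be one of {STAGES}, got {self.stage!r}")


# columns: Bufbuf Hylarb Pelcom Randal | hydroperiod (1=permanent) | %Conn | large fish
# detection symbols: E = egg masses, L = larvae, EL = both, - = none
_TABLE1 = """\
1   L  -  -  EL 1 0   2
2   -  -  -  E  1 0   0
3   L  -  L  E  1 2   3
4   -  -  -  -  1 80  6
5   -  -  -  E  0 15  5
6   L  -  -  E  1 45  6
7   -  -  -  E  1 50  8
8   L  -  L  E  1 25  4
9   -  -  -  EL 1 10  4
10  L  -  -  -  1 25  4
11  -  -  -  -  1 100 7
12  -  -  -  -  1 100 6
13  -  -  -  -  1 90  6
14  -  -  -  E  1 1.5 1
15  -  -  -  E  1 20  5
16  -  -  -  E  0 20  4
17  -  -  -  -  1 48  5
18  L  L  -  EL 1 5   6
19  -  -  -  E  0 5   0
20  L  -  -  E  1 20  5
21  -  L  L  E  0 5   0
22  -  L  -  E  0 5   0
23  -  -  -  -  1 70  7
24  -  -  -  -  1 0   5
25  L  L  L  EL 1 8   1
26  L  -  -  -  1 90  6
27  L  -  L  E  1 90  8
28  -  -  L  E  1 18  7
29  L  -  -  E  1 50  6
30  -  -  -  -  1 90  7
"""

FIXTURE_SPECIES = ("Bufbuf", "Hylarb", "Pelcom", "Randal")


def table1_fixture() -> tuple[SiteTable, list[DetectionRecord]]:
    """The packaged 30-site table: detections, hydroperiod, connectivity, fish.

    Returns the site table (hydroperiod, % days connected, large predatory
    fish richness) and one detection record per species x site x stage.
    """
    rows, records = [], []
    for line in _TABLE1.strip().splitlines():
        parts = line.split()
        site = parts[0]
        rows.append({
            "site": site,
            "hydroperiod": "permanent" if parts[5] == "1" else "ephemeral",
            "pct_connected": float(parts[6]),
            "large_fish_richness": int(parts[7]),
        })
        for sp, sym in zip(FIXTURE_SPECIES, parts[1:5]):
            records.append(DetectionRecord(sp, site, "egg_mass", "E" in sym))
            records.append(DetectionRecord(sp, site, "larvae", "L" in sym))
    df = pd.DataFrame(rows).set_index("site")
    return SiteTable(df), records


def fixture_to_json(path=None) -> str:
    """JSON export of the packaged table (sites plus detection records)."""
    table, records = table1_fixture()
    payload = {
        "sites": table.data.reset_index().to_dict(orient="records"),
        "detections": [
            {"species": r.species_id, "site": r.site_id, "stage": r.stage,
             "detected": r.detected}
            for r in records
        ],
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Naive summaries
# ---------------------------------------------------------------------------

def detection_site_count(records: Iterable[DetectionRecord], species: str, stage: str) -> int:
    """Number of distinct sites where `species` was detected at `stage`."""
    if stage not in STAGES:
        raise ValidationError(f"stage must be one of {STAGES}, got {stage!r}")
    records = list(records)
    if records:
        known = {r.species_id for r in records}
        if species not in known:
            raise KeyError(f"unknown species {species!r}; have {sorted(known)}")
    return len({r.site_id for r in records
                if r.species_id == species and r.stage == stage and r.detected})


def summary_stats(values) -> tuple[float, float, float, float]:
    """(mean, sd, min, max) with the n-1 (sample) sd denominator."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("summary_stats requires a non-empty vector")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return float(np.mean(x)), sd, float(np.min(x)), float(np.max(x))


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed summary
    tables), unlike Python's default round-half-even."""
    from decimal import ROUND_HALF_UP, Decimal
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("pearson_r needs two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])
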