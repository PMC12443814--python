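"""Data model, validation and I/O for weighted bipartite interaction data.

The central object is :class:`InteractionMatrix`: an integer matrix of visit
frequencies with plants as rows and birds as columns (the "lower" and "higher"
trophic level of a frugivory network).  Edge lists, matrices and trait tables
travel as plain-text CSV/TSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SEASONS = ("rainy", "dry", "unspecified")
SCOPES = ("overall", "rainy", "dry")

#: bird trait columns expected in a bird trait table (all strictly positive)
BIRD_TRAITS = ("bill_width", "body_length", "body_mass", "wing_length", "tail_length")
#: plant trait columns; fruit_color is a category code, FAI an ordinal 0-5
PLANT_TRAITS = (
    "fruit_diameter",
    "fruit_length",
    "fruit_mass",
    "sugar",
    "fat",
    "protein",
)


class ValidationError(ValueError):
    """Raised when input data violates the data model."""


@dataclass(frozen=True)
class VisitRecord:
    """One aggregated observation: a bird visiting a fruiting plant."""

    plant_id: str
    bird_id: str
    count: int
    season: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.plant_id or not self.bird_id:
            raise ValidationError("plant_id and bird_id must be nonempty")
        if not isinstance(self.count, (int, np.integer)) or self.count < 1:
            raise ValidationError(
                f"count must be a positive integer, got {self.count!r} "
                f"for ({self.plant_id}, {self.bird_id})"
            )
        if self.season not in SEASONS:
            raise ValidationError(
                f"unknown season {self.season!r}; expected one of {SEASONS}"
            )


@dataclass(frozen=True)
class InteractionMatrix:
    """Weighted plant x bird visit-count matrix.

    Rows are plants, columns are birds; ``w[i, j]`` is the number of visits of
    bird ``j`` to plant ``i`` within ``season_scope``.
    """

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    w: np.ndarray
    season_scope: str = "overall"

    def __post_init__(self) -> None:
        w = np.asarray(self.w)
        if w.ndim != 2 or w.shape != (len(self.rows), len(self.cols)):
            raise ValidationError(
                f"matrix shape {w.shape} does not match labels "
                f"({len(self.rows)} plants x {len(self.cols)} birds)"
            )
        if np.any(w < 0) or not np.issubdtype(w.dtype, np.integer):
            raise ValidationError("cells must be nonnegative integers")
        if self.season_scope not in SCOPES:
            raise ValidationError(f"unknown season_scope {self.season_scope!r}")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "rows", tuple(self.rows))
        object.__setattr__(self, "cols", tuple(self.cols))

    # --- derived quantities -------------------------------------------------
    @property
    def n_plants(self) -> int:
        return len(self.rows)

    @property
    def n_birds(self) -> int:
        return len(self.cols)

    @property
    def m(self) -> int:
        """Total interaction events."""
        return int(self.w.sum())

    @property
    def n_links(self) -> int:
        """Number of realized plant-bird links (nonzero cells)."""
        return int(np.count_nonzero(self.w))

    def row_totals(self) -> np.ndarray:
        return self.w.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.w.sum(axis=0)

    def require_nonempty(self) -> None:
        if self.m == 0:
            raise ValidationError("all-zero matrix: metrics are undefined")

    def drop_empty_species(self) -> "InteractionMatrix":
        """Remove rows/columns with zero interactions (e.g. in a seasonal slice)."""
        rk = self.row_totals() > 0
        ck = self.col_totals() > 0
        return replace(
            self,
            rows=tuple(r for r, k in zip(self.rows, rk) if k),
            cols=tuple(c for c, k in zip(self.cols, ck) if k),
            w=self.w[np.ix_(rk, ck)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.w, index=list(self.rows), columns=list(self.cols))


@dataclass(frozen=True)
class RichnessSummary:
    """Richness metrics: species counts, links and interaction frequency."""

    n_birds: int
    n_plants: int
    n_links: int
    m: int


def matrix_summary(matrix: InteractionMatrix) -> RichnessSummary:
    """Bird richness, plant richness, link count and total visit frequency."""
    return RichnessSummary(
        n_birds=matrix.n_birds,
        n_plants=matrix.n_plants,
        n_links=matrix.n_links,
        m=matrix.m,
    )


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

DEFAULT_DIALECT: Mapping[str, str] = {
    "plant": "plant",
    "bird": "bird",
    "count": "count",
    "season": "season",
}


def read_edge_list(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[VisitRecord]:
    """Read visit records from a CSV edge list.

    ``dialect`` maps the logical names plant/bird/count/season to the header
    names actually used in the file; the season column is optional.  Malformed
    rows raise :class:`ValidationError` naming the line number.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    path = Path(path)
    records: list[VisitRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file")
        for required in ("plant", "bird", "count"):
            if names[required] not in reader.fieldnames:
                raise ValidationError(
                    f"{path}: missing column {names[required]!r} (for {required})"
                )
        has_season = names["season"] in reader.fieldnames
        for lineno, row in enumerate(reader, start=2):
            raw_count = (row[names["count"]] or "").strip()
            try:
                count = int(raw_count)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer count {raw_count!r}"
                ) from None
            season = (row[names["season"]] or "").strip() if has_season else ""
            try:
                records.append(
                    VisitRecord(
                        plant_id=(row[names["plant"]] or "").strip(),
                        bird_id=(row[names["bird"]] or "").strip(),
                        count=count,
                        season=season if season else "unspecified",
                    )
                )
            except ValidationError as err:
                raise ValidationError(f"{path}:{lineno}: {err}") from None
    return records


def write_edge_list(records: Iterable[VisitRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plant", "bird", "count", "season"])
        for rec in records:
            writer.writerow([rec.plant_id, rec.bird_id, rec.count, rec.season])


def build_matrix(
    records: Sequence[VisitRecord],
    scope: str = "overall",
    *,
    plant_order: Sequence[str] | None = None,
    bird_order: Sequence[str] | None = None,
    keep_empty_species: bool = False,
) -> InteractionMatrix:
    """Aggregate visit records into an :class:`InteractionMatrix`.

    ``scope='overall'`` takes all records; ``'rainy'``/``'dry'`` select that
    season.  Duplicate (plant, bird) pairs are summed.  Labels are sorted
    lexicographically unless an explicit order is supplied.  By default species
    with no interaction inside the scope are dropped; ``keep_empty_species``
    retains every species seen in the full record set.
    """
    if scope not in SCOPES:
        raise ValidationError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    selected = [r for r in records if scope == "overall" or r.season == scope]
    if not selected:
        raise ValidationError(f"no records match scope {scope!r}")

    if plant_order is None:
        source = records if keep_empty_species else selected
        plants = sorted({r.plant_id for r in source})
    else:
        plants = list(plant_order)
    if bird_order is None:
        source = records if keep_empty_species else selected
        birds = sorted({r.bird_id for r in source})
    else:
        birds = list(bird_order)

    p_idx = {p: i for i, p in enumerate(plants)}
    b_idx = {b: j for j, b in enumerate(birds)}
    w = np.zeros((len(plants), len(birds)), dtype=np.int64)
    for rec in selected:
        if rec.plant_id not in p_idx or rec.bird_id not in b_idx:
            raise ValidationError(
                f"record ({rec.plant_id}, {rec.bird_id}) not in supplied label order"
            )
        w[p_idx[rec.plant_id], b_idx[rec.bird_id]] += rec.count
    return InteractionMatrix(tuple(plants), tuple(birds), w, season_scope=scope)


# ---------------------------------------------------------------------------
# Matrix and trait-table files
# ---------------------------------------------------------------------------


def read_matrix_tsv(path: str | Path, season_scope: str = "overall") -> InteractionMatrix:
    """Read a matrix TSV: first column plant labels, header row bird labels."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    w = frame.to_numpy()
    if not np.issubdtype(w.dtype, np.integer):
        if np.any(w != np.round(w)):
            raise ValidationError(f"{path}: non-integer cells")
        w = w.astype(np.int64)
    return InteractionMatrix(
        tuple(str(r) for r in frame.index),
        tuple(str(c) for c in frame.columns),
        w,
        season_scope=season_scope,
    )


def write_matrix_tsv(matrix: InteractionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_trait_table(path: str | Path, role: str) -> pd.DataFrame:
    """Read a trait CSV keyed by ``species_id`` and validate ranges.

    Birds carry morphological traits (mm / g); plants carry fruit morphology,
    nutrition, a categorical ``fruit_color`` and the ordinal fruit abundance
    index ``FAI`` in 0-5.
    """
    if role not in ("bird", "plant"):
        raise ValidationError(f"role must be 'bird' or 'plant', got {role!r}")
    frame = pd.read_csv(path).set_index("species_id")
    validate_trait_table(frame, role, source=str(path))
    return frame


def validate_trait_table(frame: pd.DataFrame, role: str, source: str = "<frame>") -> None:
    numeric = BIRD_TRAITS if role == "bird" else PLANT_TRAITS
    for col in numeric:
        if col not in frame.columns:
            raise ValidationError(f"{source}: missing trait column {col!r}")
        values = frame[col].dropna()
        if (values <= 0).any():
            bad = frame.index[frame[col] <= 0].tolist()
            raise ValidationError(f"{source}: non-positive {col} for {bad}")
    if role == "plant":
        if "FAI" not in frame.columns:
            raise ValidationError(f"{source}: missing FAI column")
        fai = frame["FAI"].dropna()
        if not fai.isin(range(6)).all():
            raise ValidationError(f"{source}: FAI must be an integer in 0..5")


def write_trait_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index_label="species_id")
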