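"""Descriptor-table ingestion and curation.

Molecular-descriptor software (PaDEL and relatives) exports wide numeric
tables — one row per chemical, one column per descriptor — that need
cleaning before modeling: descriptors whose values differ between repeated
calculations on the same structures are numerically unstable, descriptors
are brought onto a comparable scale by dividing by the training-set
maximum, a variance filter is applied to the scaled columns, and
descriptors whose magnitude in the application set dwarfs the training
range (max ratio > 100) are dropped from both sets.  A two-component PCA
of the curated matrix is used to visualise chemical-space coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import CurationError, DuplicateIdentifierError, TableMismatchError

__all__ = [
    "ChemicalRecord",
    "DescriptorTable",
    "CurationParams",
    "CurationReport",
    "load_descriptor_table",
    "load_metadata",
    "replicate_stability",
    "fit_scaling",
    "apply_scaling",
    "variance_filter",
    "ratio_filter",
    "curate",
    "pca_scores",
]


@dataclass
class ChemicalRecord:
    """Identity and measured properties of one chemical.

    ``id`` is any unique identifier (InChIKey preferred).  ``lc50`` is the
    measured 96 h LC50 in mg/L, when available; ``monoisotopic_mass`` is
    in Da.
    """

    id: str
    monoisotopic_mass: float | None = None
    smiles: str | None = None
    name: str | None = None
    lc50: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("chemical id must be nonempty")
        if self.monoisotopic_mass is not None and not self.monoisotopic_mass > 0:
            raise ValueError(f"monoisotopic_mass must be > 0, got {self.monoisotopic_mass}")
        if self.lc50 is not None and not self.lc50 > 0:
            raise ValueError(f"lc50 must be > 0, got {self.lc50}")


@dataclass
class DescriptorTable:
    """A chemicals x descriptors numeric matrix.

    ``data`` is a DataFrame indexed by chemical id with one float column
    per descriptor; missing / non-numeric cells are NaN.  ``chemicals``
    optionally carries per-chemical metadata aligned with the index.
    """

    data: pd.DataFrame
    chemicals: list[ChemicalRecord] | None = None
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateIdentifierError(f"duplicate identifier(s): {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate descriptor name(s): {dups}")
        if self.chemicals is not None:
            ids = [c.id for c in self.chemicals]
            if ids != list(self.data.index):
                raise TableMismatchError("chemical records do not match table index")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_chemicals(self) -> int:
        return self.data.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.data.shape[1]

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def restrict(self, names: Sequence[str]) -> "DescriptorTable":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"descriptors not in table: {missing}")
        return DescriptorTable(self.data.loc[:, list(names)].copy(),
                               chemicals=self.chemicals,
                               replicate_id=self.replicate_id)


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def load_descriptor_table(path: str | Path, id_column: str = "id",
                          replicate_id: int | None = None) -> DescriptorTable:
    """Read a delimited descriptor table (CSV/TSV by extension).

    All non-id columns are coerced to float; cells that do not parse
    (e.g. "NA", "Inf" markers from descriptor software) become NaN and are
    counted as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    raw = _read_delimited(path)
    if id_column not in raw.columns:
        raise KeyError(f"id column {id_column!r} not found in {path.name}")
    if raw[id_column].duplicated().any():
        dups = raw[id_column][raw[id_column].duplicated()].unique().tolist()
        raise DuplicateIdentifierError(f"duplicate identifier(s) in {path.name}: {dups}")
    values = raw.drop(columns=[id_column]).apply(pd.to_numeric, errors="coerce")
    values.index = pd.Index(raw[id_column].astype(str), name=id_column)
    return DescriptorTable(values, replicate_id=replicate_id)


_META_UNIT_ALIASES = {"g/l": "g/L", "mg/l": "mg/L", "ug/l": "μg/L", "μg/l": "μg/L",
                      "µg/l": "μg/L", "ng/l": "ng/L"}


def load_metadata(path: str | Path) -> list[ChemicalRecord]:
    """Read a chemical metadata table.

    Expected columns: ``id`` (required) plus any of ``name``, ``smiles``,
    ``inchikey``, ``monoisotopic_mass`` (Da), ``lc50``, ``lc50_unit``.
    LC50 values are converted to mg/L.
    """
    from .categorization import to_mg_per_l

    path = Path(path)
    raw = _read_delimited(path)
    if "id" not in raw.columns:
        raise KeyError(f"metadata table {path.name} lacks an 'id' column")
    records = []
    for _, row in raw.iterrows():
        lc50 = None
        if "lc50" in raw.columns and pd.notna(row.get("lc50")):
            unit = str(row.get("lc50_unit", "mg/L") or "mg/L")
            unit = _META_UNIT_ALIASES.get(unit.lower(), unit)
            lc50 = to_mg_per_l(float(row["lc50"]), unit)
        mass = row.get("monoisotopic_mass")
        records.append(ChemicalRecord(
            id=str(row["id"]),
            name=row.get("name") if pd.notna(row.get("name", None)) else None,
            smiles=row.get("smiles") if pd.notna(row.get("smiles", None)) else None,
            monoisotopic_mass=float(mass) if pd.notna(mass) else None,
            lc50=lc50,
        ))
    return records


def _check_aligned(replicates: Sequence[DescriptorTable]) -> None:
    first = replicates[0]
    for rep in replicates[1:]:
        if rep.ids != first.ids:
            raise TableMismatchError("replicates do not share identical chemicals")
        if rep.descriptor_names != first.descriptor_names:
            raise TableMismatchError("replicates do not share identical descriptors")


def replicate_stability(replicates: Sequence[DescriptorTable],
                        rel_tol: float = 1e-6,
                        abs_tol: float = 1e-9) -> set[str]:
    """Names of descriptors unstable across repeated calculations.

    A descriptor is unstable iff, for any chemical, the spread of its
    values across the replicates exceeds ``rel_tol`` relative to the
    largest absolute value among them (``abs_tol`` applies where that
    largest value is 0).  A cell missing in some but not all replicates
    also marks the descriptor unstable.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates")
    _check_aligned(replicates)
    stack = np.stack([r.data.to_numpy(dtype=float) for r in replicates])  # (r, n, p)
    nan = np.isnan(stack)
    inconsistent_nan = nan.any(axis=0) & ~nan.all(axis=0)
    with np.errstate(invalid="ignore"):
        spread = np.nanmax(stack, axis=0) - np.nanmin(stack, axis=0)
        denom = np.nanmax(np.abs(stack), axis=0)
    spread = np.where(nan.all(axis=0), 0.0, spread)
    denom = np.where(nan.all(axis=0), 0.0, denom)
    bad = np.where(denom > 0, spread > rel_tol * denom, spread > abs_tol)
    bad = bad | inconsistent_nan
    names = np.asarray(replicates[0].descriptor_names)
    return set(names[bad.any(axis=0)])


def fit_scaling(training: DescriptorTable) -> pd.Series:
    """Per-descriptor scaling factor: max |value| over the training set.

    The max *absolute* value is used so that negative-valued descriptors
    map into [-1, 1] instead of flipping sign.  Columns with factor 0
    (constant zero) must be removed before scaling is applied.
    """
    if training.n_chemicals < 1:
        raise ValueError("training table is empty")
    return training.data.abs().max(axis=0, skipna=True).fillna(0.0)


def apply_scaling(table: DescriptorTable, factors: Mapping[str, float]) -> DescriptorTable:
    """Divide each column by its training-set factor (missing stays missing)."""
    missing = [c for c in table.descriptor_names if c not in factors]
    if missing:
        raise KeyError(f"no scaling factor for: {missing}")
    fac = pd.Series({c: float(factors[c]) for c in table.descriptor_names})
    zero = fac[fac == 0].index.tolist()
    if zero:
        raise CurationError("scaling", f"zero scaling factor for retained column(s): {zero}")
    return DescriptorTable(table.data / fac, chemicals=table.chemicals,
                           replicate_id=table.replicate_id)


def variance_filter(scaled: DescriptorTable, threshold: float = 0.1,
                    direction: str = "keep_below") -> list[str]:
    """Names kept by the variance filter on max-scaled columns.

    ``keep_below`` keeps columns with sample variance (n-1 denominator)
    strictly below ``threshold``; ``keep_above`` keeps strictly above.
    """
    if scaled.n_chemicals < 2:
        raise ValueError("variance filter needs at least 2 chemicals")
    if direction not in {"keep_below", "keep_above"}:
        raise ValueError(f"unknown direction {direction!r}")
    var = scaled.data.var(axis=0, ddof=1)
    mask = var < threshold if direction == "keep_below" else var > threshold
    return [c for c in scaled.descriptor_names if bool(mask[c])]


def ratio_filter(train_factors: Mapping[str, float], app_table: DescriptorTable,
                 ratio_threshold: float = 100.0) -> set[str]:
    """Descriptors whose application-set magnitude dwarfs the training range.

    Removed iff max|application value| / training factor > threshold;
    a zero training factor with a nonzero application maximum is removed.
    """
    app_max = app_table.data.abs().max(axis=0, skipna=True).fillna(0.0)
    removed = set()
    for name in app_table.descriptor_names:
        if name not in train_factors:
            continue
        fac = float(train_factors[name])
        amax = float(app_max[name])
        if fac == 0:
            if amax > 0:
                removed.add(name)
        elif amax / fac > ratio_threshold:
            removed.add(name)
    return removed


@dataclass
class CurationParams:
    """Tunable knobs of the curation cascade (defaults are the standard run)."""

    rel_tol: float = 1e-6
    abs_tol: float = 1e-9
    variance_threshold: float = 0.1
    variance_direction: str = "keep_below"
    ratio_threshold: float = 100.0
    max_missing_fraction: float = 0.1


@dataclass
class CurationReport:
    """Which descriptors survived and why the rest were removed.

    Each removed descriptor is attributed to the first filter that caught
    it, so the removal sets are pairwise disjoint and, together with
    ``kept``, partition the original descriptor names.  Columns with too
    many missing cells or a constant-zero training column are removed
    before the main cascade and recorded separately.
    """

    kept: list[str] = field(default_factory=list)
    removed_missing: set[str] = field(default_factory=set)
    removed_unstable_replicate: set[str] = field(default_factory=set)
    removed_constant: set[str] = field(default_factory=set)
    removed_variance: set[str] = field(default_factory=set)
    removed_ratio: set[str] = field(default_factory=set)
    scaling_factors: dict[str, float] = field(default_factory=dict)

    @property
    def removal_sets(self) -> dict[str, set[str]]:
        return {
            "missing": self.removed_missing,
            "unstable_replicate": self.removed_unstable_replicate,
            "constant": self.removed_constant,
            "variance": self.removed_variance,
            "ratio": self.removed_ratio,
        }

    def n_original(self) -> int:
        return len(self.kept) + sum(len(s) for s in self.removal_sets.values())

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kept": self.kept,
            "scaling_factors": {k: self.scaling_factors[k] for k in sorted(self.scaling_factors)},
            **{f"removed_{k}": sorted(v) for k, v in self.removal_sets.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def curate(training_replicates: Sequence[DescriptorTable],
           application: DescriptorTable,
           params: CurationParams | None = None,
           ) -> tuple[DescriptorTable, DescriptorTable, CurationReport]:
    """Run the full curation cascade on a replicated training set.

    Order: missing-heavy removal -> replicate stability -> max-abs scaling
    (constant-zero removal) -> variance filter -> application/training
    ratio filter.  Each removal is attributed to the first triggering
    stage.  The first replicate provides the canonical training values;
    remaining missing cells are imputed with the training-column median.
    Returns the *scaled* curated training and application tables plus the
    report; the two tables share an identical, identically ordered
    descriptor set.
    """
    params = params or CurationParams()
    if len(training_replicates) != 3:
        raise CurationError("input", f"expected 3 training replicates, got {len(training_replicates)}")
    _check_aligned(training_replicates)
    all_names = training_replicates[0].descriptor_names
    extra = [c for c in all_names if c not in set(application.descriptor_names)]
    if extra:
        raise CurationError("input", f"application table lacks descriptors: {extra[:5]}")

    report = CurationReport()
    train = training_replicates[0].data.copy()
    surviving = list(all_names)

    # stage 0: columns with too many missing cells in the canonical replicate
    miss_frac = train.isna().mean(axis=0)
    report.removed_missing = {c for c in surviving if miss_frac[c] > params.max_missing_fraction}
    surviving = [c for c in surviving if c not in report.removed_missing]

    # stage 1: replicate stability
    unstable = replicate_stability(training_replicates, params.rel_tol, params.abs_tol)
    report.removed_unstable_replicate = unstable & set(surviving)
    surviving = [c for c in surviving if c not in report.removed_unstable_replicate]

    # impute remaining missing cells by the training-column median
    train = train[surviving]
    medians = train.median(axis=0)
    train = train.fillna(medians)
    app = application.data[surviving].fillna(medians)

    # stage 2: scaling (constant-zero columns cannot be scaled)
    factors = fit_scaling(DescriptorTable(train))
    report.removed_constant = set(factors[factors == 0].index)
    surviving = [c for c in surviving if c not in report.removed_constant]
    train, app, factors = train[surviving], app[surviving], factors[surviving]
    train_scaled = train / factors
    app_scaled = app / factors

    # stage 3: variance filter on the scaled training columns
    kept_var = set(variance_filter(DescriptorTable(train_scaled),
                                   params.variance_threshold, params.variance_direction))
    report.removed_variance = {c for c in surviving if c not in kept_var}
    surviving = [c for c in surviving if c in kept_var]

    # stage 4: application/training magnitude ratio (on unscaled values)
    removed_ratio = ratio_filter(factors, DescriptorTable(app[surviving]),
                                 params.ratio_threshold)
    report.removed_ratio = removed_ratio & set(surviving)
    surviving = [c for c in surviving if c not in report.removed_ratio]

    report.kept = surviving
    report.scaling_factors = {c: float(factors[c]) for c in surviving}
    curated_train = DescriptorTable(train_scaled[surviving],
                                    chemicals=training_replicates[0].chemicals)
    curated_app = DescriptorTable(app_scaled[surviving], chemicals=application.chemicals)
    return curated_train, curated_app, report


def pca_scores(matrix: np.ndarray | pd.DataFrame, n_components: int = 2
               ) -> tuple[np.ndarray, np.ndarray]:
    """Principal-component scores of a curated matrix (mean-centered).

    Returns (scores, explained variance fractions); fractions are
    non-increasing and the score columns have zero mean.
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; curate/impute first")
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds min(n, p)={min(X.shape)}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
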