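"""Synthetic chemicals, descriptor matrices and LC50 responses.

Real descriptor tables for acute fish toxicity work are large (hundreds
of chemicals, thousands of partially redundant descriptors) and cannot
ship with the package, so this module emulates their structure: a latent
factor model produces correlated descriptor blocks, eight designated
descriptors carry the toxicity signal, log10 LC50 spans roughly -3 to +5
log(mg/L), monoisotopic masses are uniform in ~50-1000 Da, replicate
"calculations" differ by tiny numerical jitter except for a configurable
fraction of deliberately unstable descriptors, and the application set is
half in-distribution, half shifted out of the training chemical space.

Everything is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .curation import ChemicalRecord, DescriptorTable

__all__ = [
    "GeneratorConfig",
    "SyntheticTraining",
    "SyntheticApplication",
    "generate_training",
    "generate_application",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-chemical generator.

    Defaults mirror the scale of a curated acute fish toxicity study:
    ~907 chemicals with ~2036 curated descriptors, log LC50 spanning
    -3..+5 log(mg/L) and masses 50-1000 Da.  ``response`` selects a
    smooth descriptor->log LC50 map (sums of ridge functions) or a
    discontinuous one (a thresholded latent score mapped to
    category-specific mean log LC50 values).
    """

    n_chemicals: int = 907
    n_descriptors: int = 2036
    n_latent: int = 20
    n_signal: int = 8
    noise_sd: float = 0.3
    response: str = "smooth"  # or "discontinuous"
    mass_range: tuple[float, float] = (50.0, 1000.0)
    log_lc50_range: tuple[float, float] = (-3.0, 5.0)
    category_log_means: tuple[float, ...] = (-1.5, 0.5, 2.5)
    category_spread: float = 1.2
    category_weights: tuple[float, ...] | None = None
    unstable_fraction: float = 0.02
    shift_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal > self.n_latent:
            raise ValueError("n_signal must be <= n_latent")
        if self.n_latent > self.n_descriptors:
            raise ValueError("n_latent must be <= n_descriptors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.mass_range
        if not (0 < lo < hi):
            raise ValueError("mass_range must be positive and ordered")
        if self.response not in {"smooth", "discontinuous"}:
            raise ValueError(f"unknown response kind {self.response!r}")
        if not 0 <= self.unstable_fraction <= 1:
            raise ValueError("unstable_fraction must be in [0, 1]")
        if self.category_weights is not None:
            if len(self.category_weights) != len(self.category_log_means):
                raise ValueError("category_weights must match category_log_means")
            if abs(sum(self.category_weights) - 1.0) > 1e-9:
                raise ValueError("category_weights must sum to 1")


@dataclass
class _Structure:
    """Seed-determined loadings shared by training and application draws."""

    block: np.ndarray          # latent index per descriptor
    loading: np.ndarray        # loading per descriptor
    col_noise: np.ndarray      # idiosyncratic noise sd per descriptor
    signal_coef: np.ndarray    # response coefficients of the signal descriptors
    unstable_cols: np.ndarray  # indices of replicate-unstable descriptors
    shift_direction: np.ndarray  # unit vector in latent space


def _structure(config: GeneratorConfig) -> _Structure:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    p, L, s = config.n_descriptors, config.n_latent, config.n_signal
    block = rng.integers(0, L, size=p)
    loading = rng.uniform(0.5, 1.5, size=p) * rng.choice([-1.0, 1.0], size=p)
    col_noise = np.full(p, 0.3)
    # the signal descriptors are tight, one-to-one proxies of distinct latents
    block[:s] = np.arange(s)
    loading[:s] = 1.0
    col_noise[:s] = 0.05
    # geometrically decaying response weights: descriptor importance in real
    # QSAR data is strongly skewed (one or two variables dominate)
    signal_coef = 2.0 ** -(np.arange(s) % max(s // 2, 1))
    n_unstable = int(round(config.unstable_fraction * p))
    unstable_cols = rng.choice(p, size=n_unstable, replace=False)
    v = rng.normal(size=L)
    return _Structure(block=block, loading=loading, col_noise=col_noise,
                      signal_coef=signal_coef, unstable_cols=unstable_cols,
                      shift_direction=v / np.linalg.norm(v))


def _descriptors(Z: np.ndarray, struct: _Structure, rng: np.random.Generator
                 ) -> np.ndarray:
    n = Z.shape[0]
    p = struct.block.shape[0]
    X = Z[:, struct.block] * struct.loading
    X += rng.normal(size=(n, p)) * struct.col_noise
    return X


def _descriptor_names(p: int) -> list[str]:
    return [f"d{j + 1:04d}" for j in range(p)]


def _response(config: GeneratorConfig, struct: _Structure, X: np.ndarray,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray | None]:
    """(log LC50, category indices or None) from the signal descriptors."""
    S = X[:, :config.n_signal]
    lo, hi = config.log_lc50_range
    if config.response == "smooth":
        raw = (S * struct.signal_coef).sum(axis=1) \
            + (np.tanh(S) * struct.signal_coef).sum(axis=1)
        span = raw.max() - raw.min()
        y = lo + (raw - raw.min()) / (span if span > 0 else 1.0) * (hi - lo)
        cats = None
    else:
        # half the signal descriptors drive the category step, the other half
        # a smooth within-category spread, so log LC50 jumps between
        # category-specific means yet still fills the hazard bins the way a
        # continuous measured-LC50 distribution does
        half = max(config.n_signal // 2, 1)
        score = (S[:, :half] * struct.signal_coef[:half]).sum(axis=1)
        within = (S[:, half:] * struct.signal_coef[half:config.n_signal]).sum(axis=1)
        k = len(config.category_log_means)
        weights = config.category_weights or tuple(1.0 / k for _ in range(k))
        cuts = np.quantile(score, np.cumsum(weights)[:-1])
        cats = np.searchsorted(cuts, score, side="right")
        y = np.asarray(config.category_log_means)[cats]
        sd = within.std()
        if config.category_spread > 0 and sd > 0:
            y = y + config.category_spread * np.tanh(within / sd)
    return y + rng.normal(size=X.shape[0]) * config.noise_sd, cats


@dataclass
class SyntheticTraining:
    """Triplicate descriptor tables plus ground-truth responses."""

    replicates: list[DescriptorTable]
    records: list[ChemicalRecord]
    log_lc50: np.ndarray
    categories: np.ndarray | None
    signal_descriptors: list[str]
    config: GeneratorConfig

    @property
    def table(self) -> DescriptorTable:
        """The canonical (first-replicate) descriptor table."""
        return self.replicates[0]

    @property
    def masses(self) -> np.ndarray:
        return np.asarray([r.monoisotopic_mass for r in self.records])


def generate_training(config: GeneratorConfig) -> SyntheticTraining:
    """Draw a triplicate synthetic training set from the configuration.

    Replicates 2 and 3 equal replicate 1 up to ~1e-8 relative jitter,
    except that round(unstable_fraction * p) randomly chosen descriptors
    are rescaled by fixed large factors — exactly those columns fail a
    replicate-stability check at the default tolerance.
    """
    struct = _structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n, p = config.n_chemicals, config.n_descriptors
    Z = rng.normal(size=(n, config.n_latent))
    X = _descriptors(Z, struct, rng)
    y, cats = _response(config, struct, X, rng)
    masses = rng.uniform(*config.mass_range, size=n)

    ids = [f"chem{i + 1:05d}" for i in range(n)]
    names = _descriptor_names(p)
    records = [ChemicalRecord(id=i, monoisotopic_mass=float(m), lc50=float(10.0 ** v))
               for i, m, v in zip(ids, masses, y)]

    replicates = []
    for rep, big_factor in ((1, 1.0), (2, 1.5), (3, 0.7)):
        Xr = X.copy()
        if rep > 1:
            Xr *= 1.0 + 1e-8 * rng.standard_normal(size=X.shape)
            Xr[:, struct.unstable_cols] = X[:, struct.unstable_cols] * big_factor
        replicates.append(DescriptorTable(
            pd.DataFrame(Xr, index=pd.Index(ids, name="id"), columns=names),
            chemicals=records, replicate_id=rep))
    return SyntheticTraining(replicates=replicates, records=records, log_lc50=y,
                             categories=cats,
                             signal_descriptors=names[:config.n_signal],
                             config=config)


@dataclass
class SyntheticApplication:
    """An application set, half of it shifted out of the training space."""

    table: DescriptorTable
    records: list[ChemicalRecord]
    shifted_ids: list[str]
    config: GeneratorConfig

    @property
    def masses(self) -> np.ndarray:
        return np.asarray([r.monoisotopic_mass for r in self.records])


def generate_application(config: GeneratorConfig,
                         shift_sd: float | None = None,
                         n_chemicals: int | None = None) -> SyntheticApplication:
    """Draw an application set matching a training configuration.

    The first half of the chemicals comes from the training descriptor
    distribution; the second half is displaced by ``shift_sd`` latent
    standard deviations along a fixed random direction, i.e. designed to
    fall outside the training applicability domain when the shift is
    large.
    """
    struct = _structure(config)
    if shift_sd is None:
        shift_sd = config.shift_sd
    n = n_chemicals if n_chemicals is not None else config.n_chemicals
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    Z = rng.normal(size=(n, config.n_latent))
    n_shift = n // 2
    shifted = np.arange(n - n_shift, n)
    Z[shifted] += shift_sd * struct.shift_direction
    X = _descriptors(Z, struct, rng)
    masses = rng.uniform(*config.mass_range, size=n)
    ids = [f"app{i + 1:05d}" for i in range(n)]
    records = [ChemicalRecord(id=i, monoisotopic_mass=float(m))
               for i, m in zip(ids, masses)]
    table = DescriptorTable(pd.DataFrame(
        X, index=pd.Index(ids, name="id"),
        columns=_descriptor_names(config.n_descriptors)), chemicals=records)
    return SyntheticApplication(table=table, records=records,
                                shifted_ids=[ids[i] for i in shifted],
                                config=config)


# ---------------------------------------------------------------------------
# Deterministic in-memory fixtures used by the test-suite and worked examples.
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("curation6", "blobs4", "ad5")


@dataclass
class CurationFixture:
    replicates: list[DescriptorTable]
    application: DescriptorTable
    records: list[ChemicalRecord]
    expected_kept: list[str]
    expected_unstable: set[str]
    expected_variance: set[str]
    expected_ratio: set[str]


@dataclass
class BlobsFixture:
    points: np.ndarray   # (400, 2): (log10 LC50 mg/L, mass Da)
    labels: np.ndarray   # true component of each point
    centers: np.ndarray  # (4, 2)
    sigmas: np.ndarray   # per-dimension component sd


@dataclass
class ADFixture:
    train: pd.DataFrame    # 8 training chemicals x 4 descriptors
    query: pd.DataFrame    # 5 query chemicals
    subsets: dict[str, list[str]]


def _make_curation6() -> CurationFixture:
    rng = np.random.default_rng(42)
    n, ids = 10, [f"c{i + 1:02d}" for i in range(10)]
    cols = {
        # D1: replicate-unstable (replicates 2/3 rescale it)
        "D1": rng.uniform(4.0, 6.0, n),
        # D2: alternating 0/10 -> scaled sample variance 5/18 >= 0.1 -> variance-removed
        "D2": np.tile([0.0, 10.0], 5),
        # D3: training max ~1 but the application set reaches 150 -> ratio-removed
        "D3": rng.uniform(0.5, 1.0, n),
        # D4-D6: stable, low-variance, in-range -> kept
        "D4": rng.uniform(8.0, 10.0, n),
        "D5": -rng.uniform(8.0, 10.0, n),
        "D6": rng.uniform(8.0, 10.0, n),
    }
    base = pd.DataFrame(cols, index=pd.Index(ids, name="id"))
    records = [ChemicalRecord(id=i, monoisotopic_mass=float(m), lc50=float(l))
               for i, m, l in zip(ids, rng.uniform(50, 1000, n),
                                  10.0 ** rng.uniform(-3, 5, n))]
    reps = []
    for rep, factor in ((1, 1.0), (2, 1.5), (3, 0.7)):
        df = base.copy()
        df["D1"] = base["D1"] * factor
        reps.append(DescriptorTable(df, chemicals=records, replicate_id=rep))
    app_ids = [f"a{i + 1:02d}" for i in range(5)]
    app = pd.DataFrame({
        "D1": rng.uniform(4.0, 6.0, 5),
        "D2": rng.uniform(0.0, 10.0, 5),
        "D3": np.array([0.7, 0.8, 150.0, 0.6, 0.9]),
        "D4": rng.uniform(7.0, 10.0, 5),
        "D5": -rng.uniform(7.0, 10.0, 5),
        "D6": rng.uniform(7.0, 10.0, 5),
    }, index=pd.Index(app_ids, name="id"))
    return CurationFixture(
        replicates=reps, application=DescriptorTable(app), records=records,
        expected_kept=["D4", "D5", "D6"], expected_unstable={"D1"},
        expected_variance={"D2"}, expected_ratio={"D3"})


def _make_blobs4() -> BlobsFixture:
    # per-dimension sd = 0.05 x the smallest between-center separation
    centers = np.array([[-2.0, 100.0], [0.0, 400.0], [2.0, 600.0], [4.0, 900.0]])
    sigmas = 0.05 * np.array([2.0, 200.0])
    rng = np.random.default_rng(7)
    points, labels = [], []
    for i, c in enumerate(centers):
        points.append(c + rng.normal(size=(100, 2)) * sigmas)
        labels.extend([i] * 100)
    return BlobsFixture(points=np.vstack(points), labels=np.asarray(labels),
                        centers=centers, sigmas=sigmas)


def _make_ad5() -> ADFixture:
    rng = np.random.default_rng(3)
    names = ["d1", "d2", "d3", "d4"]
    train = pd.DataFrame(rng.uniform(-1, 1, size=(8, 4)),
                         index=pd.Index([f"t{i + 1}" for i in range(8)], name="id"),
                         columns=names)
    query = pd.DataFrame(
        np.vstack([rng.uniform(-1, 1, size=(3, 4)),        # in-range queries
                   rng.uniform(4, 6, size=(2, 4))]),       # far outside
        index=pd.Index([f"q{i + 1}" for i in range(5)], name="id"), columns=names)
    subsets = {"full": names, "regression": ["d1", "d2"],
               "classification": ["d2", "d3", "d4"]}
    return ADFixture(train=train, query=query, subsets=subsets)


_FIXTURE_BUILDERS = {"curation6": _make_curation6, "blobs4": _make_blobs4,
                     "ad5": _make_ad5}


def make_fixture(name: str):
    """Return one of the deterministic tiny data sets used by the tests."""
    if name not in _FIXTURE_BUILDERS:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FIXTURE_BUILDERS)}")
    return _FIXTURE_BUILDERS[name]()
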