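"""Solvent descriptor model: σ-profiles, segmentation, mixing, PCA features.

A solvent is represented by 17 tabulated molecular descriptors — 14 scalar
physico-chemical properties plus the areas of the COSMO screening-charge
density profile ("σ-profile") segmented into three regions (σ̄₁–σ̄₃).  A
five-segment variant (σ₁–σ₅) is kept alongside.  Principal components of the
autoscaled 17-descriptor block (t₁–t₄) provide low-dimensional features for
the Gaussian-process surrogates; the six canonical feature sets used by the
surrogate models are exposed as :data:`MODEL_FEATURES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, MissingFeatureError

# --------------------------------------------------------------------------
# Descriptor schema
# --------------------------------------------------------------------------

#: The 14 scalar descriptors, in schema order (units in parentheses).
SCALAR_DESCRIPTORS: tuple[str, ...] = (
    "molecular_weight",            # g/mol
    "density",                     # g/mL
    "molar_volume",                # mL/mol
    "refractive_index",            # —
    "molecular_refractive_power",  # mL/mol
    "dielectric_constant",         # —
    "dipole_moment",               # D
    "melting_point_C",             # °C
    "boiling_point_C",             # °C
    "viscosity_cP",                # cP
    "ln_P_ow",                     # octanol–water partition, —
    "vapour_pressure_mbar",        # mbar
    "henry_H2_bar",                # Henry's constant of H2, bar
    "ln_gamma_substrate",          # activity coefficient of the substrate, —
)

#: Five-segment σ-profile areas (Å²).
SIGMA5_COLUMNS: tuple[str, ...] = tuple(f"sigma_{i}" for i in range(1, 6))
#: Three-segment σ-profile areas σ̄₁–σ̄₃ (Å²).
SIGMA3_COLUMNS: tuple[str, ...] = tuple(f"sigma_bar_{i}" for i in range(1, 4))

#: The 17 descriptors entering PCA: the σ̄ (three-segment) areas are used in
#: preference over σ₁–σ₅ within the 17.
PCA_DESCRIPTORS: tuple[str, ...] = SCALAR_DESCRIPTORS + SIGMA3_COLUMNS

ALL_DESCRIPTOR_COLUMNS: tuple[str, ...] = (
    SCALAR_DESCRIPTORS + SIGMA5_COLUMNS + SIGMA3_COLUMNS
)

#: Default σ cut points (e Å⁻²) for the three-segment split.
SIGMA3_BOUNDARIES: tuple[float, ...] = (-0.010, 0.010)
#: Default σ cut points (e Å⁻²) for the five-segment split.
SIGMA5_BOUNDARIES: tuple[float, ...] = (-0.015, -0.005, 0.005, 0.015)

#: Gas constant in kJ mol⁻¹ K⁻¹.
R_KJ = 8.314462618e-3


# --------------------------------------------------------------------------
# σ-profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SigmaProfile:
    """Screening-charge-density profile: p(σ) in Å² per (e Å⁻²) on a σ grid."""

    sigma: np.ndarray   # strictly increasing, e Å⁻²
    density: np.ndarray  # ≥ 0, aligned with sigma

    def __post_init__(self):
        sigma = np.asarray(self.sigma, dtype=float)
        density = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "density", density)
        if sigma.ndim != 1 or sigma.size < 2:
            raise InvalidArgumentError("profile needs at least two grid points")
        if density.shape != sigma.shape:
            raise InvalidArgumentError("sigma and density must be aligned")
        if np.any(np.diff(sigma) <= 0):
            raise InvalidArgumentError("sigma grid must be strictly increasing")
        if np.any(density < 0):
            raise InvalidArgumentError("densities must be non-negative")
        if self.total_area() <= 0:
            raise InvalidArgumentError("total integrated area must be positive")

    def total_area(self) -> float:
        """Trapezoidal integral of p(σ) over the grid (Å²)."""
        return float(np.trapezoid(self.density, self.sigma))

    def regrid(self, new_sigma: np.ndarray) -> "SigmaProfile":
        """Linear interpolation onto ``new_sigma``; zero outside the support."""
        dens = np.interp(new_sigma, self.sigma, self.density, left=0.0, right=0.0)
        return SigmaProfile(np.asarray(new_sigma, dtype=float), dens)


def segment_sigma_profile(
    profile: SigmaProfile, boundaries: Sequence[float]
) -> np.ndarray:
    """Areas under the profile between consecutive cut points.

    Returns ``len(boundaries) + 1`` areas covering
    (−∞, b₁), [b₁, b₂), …, [b_last, ∞); the profile is zero outside its grid,
    so outer segments only accumulate area inside the grid span.  Integration
    is trapezoidal with the density linearly interpolated at each cut, which
    makes the areas sum exactly to the total profile area.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.ndim != 1 or b.size == 0:
        raise InvalidArgumentError("at least one boundary required")
    if np.any(np.diff(b) <= 0):
        raise InvalidArgumentError("boundaries must be strictly increasing")
    sigma, dens = profile.sigma, profile.density
    inner = b[(b > sigma[0]) & (b < sigma[-1])]
    grid = np.union1d(sigma, inner)
    dgrid = np.interp(grid, sigma, dens)
    # cumulative trapezoid areas on the augmented grid
    seg = 0.5 * (dgrid[1:] + dgrid[:-1]) * np.diff(grid)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    # cumulative area up to each boundary (clipped to the grid span)
    cut_cum = np.interp(np.clip(b, sigma[0], sigma[-1]), grid, cum)
    edges = np.concatenate([[0.0], cut_cum, [cum[-1]]])
    areas = np.diff(edges)
    return np.maximum(areas, 0.0)


def mix_sigma_profiles(
    profiles: Sequence[SigmaProfile],
    fractions: Sequence[float],
    grid: np.ndarray | None = None,
) -> SigmaProfile:
    """Volume-fraction-weighted linear combination of σ-profiles.

    Profiles are re-gridded (linear interpolation, zero outside support) to a
    common σ grid — the union of the input grids unless ``grid`` is given —
    and their densities combined pointwise.  Segment areas of the mixture are
    therefore the fraction-weighted sums of the pure-component areas.
    """
    profiles = list(profiles)
    frac = np.asarray(fractions, dtype=float)
    if len(profiles) == 0:
        raise InvalidArgumentError("at least one profile required")
    if frac.shape != (len(profiles),):
        raise InvalidArgumentError("one fraction per profile required")
    if np.any(frac < 0):
        raise InvalidArgumentError("fractions must be non-negative")
    if abs(frac.sum() - 1.0) > 1e-8:
        raise InvalidArgumentError(f"fractions must sum to 1 (got {frac.sum()!r})")
    if grid is None:
        grid = profiles[0].sigma
        for p in profiles[1:]:
            grid = np.union1d(grid, p.sigma)
    grid = np.asarray(grid, dtype=float)
    dens = np.zeros_like(grid)
    for f, p in zip(frac, profiles):
        dens += f * np.interp(grid, p.sigma, p.density, left=0.0, right=0.0)
    return SigmaProfile(grid, dens)


# --------------------------------------------------------------------------
# Solvent records and library
# --------------------------------------------------------------------------

@dataclass
class SolventRecord:
    """One solvent: identity, 14 scalar descriptors, σ-segment areas.

    Missing descriptor values are stored as NaN; ``missing_mask`` reports
    them per descriptor name.
    """

    id: str
    name: str
    scalars: dict[str, float]
    sigma5: np.ndarray  # σ₁–σ₅ areas, Å²
    sigma3: np.ndarray  # σ̄₁–σ̄₃ areas, Å²

    def __post_init__(self):
        self.sigma5 = np.asarray(self.sigma5, dtype=float)
        self.sigma3 = np.asarray(self.sigma3, dtype=float)
        if self.sigma5.shape != (5,) or self.sigma3.shape != (3,):
            raise InvalidArgumentError("sigma5/sigma3 must have 5 and 3 areas")
        for arr in (self.sigma5, self.sigma3):
            finite = arr[np.isfinite(arr)]
            if np.any(finite < 0):
                raise InvalidArgumentError("segment areas must be non-negative")
        # both segmentations integrate the same profile
        if np.all(np.isfinite(self.sigma5)) and np.all(np.isfinite(self.sigma3)):
            t5, t3 = self.sigma5.sum(), self.sigma3.sum()
            if t5 > 0 and abs(t5 - t3) > 1e-8 * max(t5, t3):
                raise InvalidArgumentError(
                    f"solvent {self.id!r}: σ₅ total {t5!r} != σ̄₃ total {t3!r}"
                )

    @property
    def missing_mask(self) -> dict[str, bool]:
        mask = {k: not np.isfinite(v) for k, v in self.scalars.items()}
        for cols, arr in ((SIGMA5_COLUMNS, self.sigma5), (SIGMA3_COLUMNS, self.sigma3)):
            for c, v in zip(cols, arr):
                mask[c] = not np.isfinite(v)
        return mask

    def value(self, column: str) -> float:
        if column in self.scalars:
            return float(self.scalars[column])
        if column in SIGMA5_COLUMNS:
            return float(self.sigma5[SIGMA5_COLUMNS.index(column)])
        if column in SIGMA3_COLUMNS:
            return float(self.sigma3[SIGMA3_COLUMNS.index(column)])
        raise MissingFeatureError(self.id, column)


class SolventLibrary:
    """A collection of :class:`SolventRecord` with unique ids.

    Internally backed by a :class:`pandas.DataFrame` (index = solvent id) so
    that vectorised featurization and filtering stay cheap.
    """

    def __init__(self, records: Iterable[SolventRecord], provenance: str = ""):
        records = list(records)
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidArgumentError(f"duplicate solvent ids: {dupes}")
        self.provenance = provenance
        self._records = {r.id: r for r in records}
        rows = {}
        for r in records:
            row = {"name": r.name}
            row.update({c: r.scalars.get(c, np.nan) for c in SCALAR_DESCRIPTORS})
            row.update(dict(zip(SIGMA5_COLUMNS, r.sigma5)))
            row.update(dict(zip(SIGMA3_COLUMNS, r.sigma3)))
            rows[r.id] = row
        cols = ["name", *ALL_DESCRIPTOR_COLUMNS]
        self.table = pd.DataFrame.from_dict(rows, orient="index", dtype=object)
        self.table = self.table.reindex(columns=cols)
        self.table.index.name = "id"
        for c in ALL_DESCRIPTOR_COLUMNS:
            self.table[c] = pd.to_numeric(self.table[c])

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, solvent_id: str) -> bool:
        return solvent_id in self._records

    def __getitem__(self, solvent_id: str) -> SolventRecord:
        return self._records[solvent_id]

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def coverage(self) -> pd.Series:
        """Fraction of non-missing entries per descriptor column."""
        return self.table[list(ALL_DESCRIPTOR_COLUMNS)].notna().mean()

    def descriptor_matrix(self, columns: Sequence[str]) -> pd.DataFrame:
        unknown = [c for c in columns if c not in self.table.columns]
        if unknown:
            raise InvalidArgumentError(f"unknown descriptor columns: {unknown}")
        return self.table[list(columns)].astype(float)

    def subset(self, ids: Sequence[str]) -> "SolventLibrary":
        return SolventLibrary([self._records[i] for i in ids], self.provenance)


# --------------------------------------------------------------------------
# Library filtering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterRule:
    """A named row predicate over descriptor columns.

    ``predicate`` maps the library table to a boolean keep-mask; ``columns``
    lists the descriptor columns it reads (validated before application).
    """

    name: str
    columns: tuple[str, ...]
    predicate: Callable[[pd.DataFrame], np.ndarray]


def completeness_rule(columns: Sequence[str] = ALL_DESCRIPTOR_COLUMNS) -> FilterRule:
    """Keep rows with no missing value in ``columns``."""
    cols = tuple(columns)
    return FilterRule(
        "complete", cols, lambda t: t[list(cols)].notna().all(axis=1).to_numpy()
    )


def min_value_rule(column: str, minimum: float) -> FilterRule:
    """Keep rows with ``column`` ≥ ``minimum`` (NaN rows are kept)."""
    return FilterRule(
        f"{column}>={minimum}",
        (column,),
        lambda t: ~(t[column] < minimum).to_numpy(),
    )


def max_value_rule(column: str, maximum: float) -> FilterRule:
    """Keep rows with ``column`` ≤ ``maximum`` (NaN rows are kept)."""
    return FilterRule(
        f"{column}<={maximum}",
        (column,),
        lambda t: ~(t[column] > maximum).to_numpy(),
    )


def apply_library_filters(
    library: SolventLibrary, rules: Sequence[FilterRule]
) -> tuple[SolventLibrary, dict[str, int]]:
    """Apply rules in order; returns the filtered library and per-rule removal counts."""
    keep_ids = list(library.ids)
    removed: dict[str, int] = {}
    for rule in rules:
        sub = library.subset(keep_ids) if keep_ids else library.subset([])
        for c in rule.columns:
            if c not in library.table.columns:
                raise InvalidArgumentError(
                    f"filter rule {rule.name!r} references unknown column {c!r}"
                )
        if not keep_ids:
            removed[rule.name] = 0
            continue
        mask = np.asarray(rule.predicate(sub.table), dtype=bool)
        removed[rule.name] = int((~mask).sum())
        keep_ids = [i for i, k in zip(keep_ids, mask) if k]
    return library.subset(keep_ids), removed


# --------------------------------------------------------------------------
# PCA feature engineering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAModel:
    """Autoscaled PCA of a descriptor block.

    ``components`` holds one loading vector per row (k × p, orthonormal rows);
    sign convention: the largest-magnitude element of each loading is positive.
    """

    feature_names: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean) / self.scale
        return Z @ self.components.T


def fit_pca(
    library: SolventLibrary | pd.DataFrame,
    columns: Sequence[str] = PCA_DESCRIPTORS,
    k: int = 4,
) -> PCAModel:
    """PCA on the autoscaled (z-scored, ddof=1) descriptor block.

    Rows with any missing value in ``columns`` are excluded from the fit.
    Explained-variance ratios are eigenvalue fractions of the correlation
    matrix of the complete rows.
    """
    if k < 1:
        raise InvalidArgumentError("k must be ≥ 1")
    table = library.table if isinstance(library, SolventLibrary) else library
    unknown = [c for c in columns if c not in table.columns]
    if unknown:
        raise InvalidArgumentError(f"unknown descriptor columns: {unknown}")
    X = table[list(columns)].astype(float)
    if X.isna().all(axis=0).any():
        bad = [c for c in columns if X[c].isna().all()]
        raise InvalidArgumentError(f"all-missing descriptor columns: {bad}")
    complete = X.dropna(axis=0)
    n, p = complete.shape
    if n < k + 1:
        raise InvalidArgumentError(
            f"need ≥ k+1 = {k + 1} complete rows, have {n}"
        )
    M = complete.to_numpy()
    mean = M.mean(axis=0)
    scale = M.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = [c for c, s in zip(columns, scale) if s == 0]
        raise InvalidArgumentError(f"zero-variance descriptor columns: {bad}")
    Z = (M - mean) / scale
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, p) * np.finfo(float).eps)) if s.size else 0
    if k > rank:
        raise InvalidArgumentError(f"k={k} exceeds data rank {rank}")
    evr = s**2 / np.sum(s**2)
    comp = Vt[:k].copy()
    # deterministic sign: largest-|.| element of each loading made positive
    for i in range(k):
        j = int(np.argmax(np.abs(comp[i])))
        if comp[i, j] < 0:
            comp[i] = -comp[i]
    return PCAModel(
        feature_names=tuple(columns),
        mean=mean,
        scale=scale,
        components=comp,
        explained_variance_ratio=evr[:k],
    )


# --------------------------------------------------------------------------
# Feature specifications (surrogate models 1–6)
# --------------------------------------------------------------------------

PC_COLUMNS: tuple[str, ...] = ("t1", "t2", "t3", "t4")

#: Canonical feature sets of the six surrogate model variants.
MODEL_FEATURES: dict[int, tuple[str, ...]] = {
    1: SIGMA5_COLUMNS,
    2: SIGMA3_COLUMNS,
    3: PC_COLUMNS,
    4: PC_COLUMNS[:3],
    5: PC_COLUMNS[:2],
    6: PC_COLUMNS[:1],
}


@dataclass(frozen=True)
class FeatureSpec:
    """Model id (1–6) → ordered feature names, with the PCA model when needed."""

    model_id: int
    features: tuple[str, ...]
    pca: PCAModel | None = None

    def __post_init__(self):
        if self.model_id not in MODEL_FEATURES:
            raise InvalidArgumentError(f"unknown model id {self.model_id}")
        if self.features != MODEL_FEATURES[self.model_id]:
            raise InvalidArgumentError(
                f"model {self.model_id} features must be {MODEL_FEATURES[self.model_id]}"
            )
        if self.uses_pca and self.pca is None:
            raise InvalidArgumentError(
                f"model {self.model_id} uses principal components; a PCAModel is required"
            )
        if self.pca is not None and self.uses_pca:
            need = max(int(f[1]) for f in self.features)
            if self.pca.k < need:
                raise InvalidArgumentError(
                    f"PCAModel has {self.pca.k} components, model needs {need}"
                )

    @property
    def uses_pca(self) -> bool:
        return self.features[0].startswith("t")


def feature_spec(model_id: int, pca: PCAModel | None = None) -> FeatureSpec:
    return FeatureSpec(model_id, MODEL_FEATURES[model_id], pca)


def featurize(
    records: SolventLibrary | Sequence[SolventRecord], spec: FeatureSpec
) -> pd.DataFrame:
    """Feature matrix (rows = solvents, columns = ``spec.features``)."""
    if isinstance(records, SolventLibrary):
        records = list(records)
    else:
        records = list(records)
    ids = [r.id for r in records]
    if spec.uses_pca:
        pca = spec.pca
        raw = np.empty((len(records), len(pca.feature_names)))
        for i, r in enumerate(records):
            for j, c in enumerate(pca.feature_names):
                v = r.value(c)
                if not np.isfinite(v):
                    raise MissingFeatureError(r.id, c)
                raw[i, j] = v
        scores = pca.transform(raw)
        idx = [int(f[1]) - 1 for f in spec.features]
        mat = scores[:, idx]
    else:
        mat = np.empty((len(records), len(spec.features)))
        for i, r in enumerate(records):
            for j, c in enumerate(spec.features):
                v = r.value(c)
                if not np.isfinite(v):
                    raise MissingFeatureError(r.id, c)
                mat[i, j] = v
    return pd.DataFrame(mat, index=pd.Index(ids, name="id"), columns=list(spec.features))


# --------------------------------------------------------------------------
# d.e. ↔ ΔΔG‡ conversion
# --------------------------------------------------------------------------

def de_to_ddg(de, temperature_K):
    """ΔΔG‡ (kJ mol⁻¹) between diastereomeric transition states from d.e.

    Under Curtin–Hammett kinetics the diastereomer ratio is a Boltzmann ratio,
    giving ΔΔG = R·T·ln((1+de)/(1−de)); positive ΔΔG means the major
    diastereomer is favoured.  ``de`` is a fraction in (−1, 1).
    """
    de = np.asarray(de, dtype=float)
    T = np.asarray(temperature_K, dtype=float)
    if np.any(T <= 0):
        raise InvalidArgumentError("temperature must be positive (K)")
    if np.any(np.abs(de) >= 1):
        raise InvalidArgumentError("|de| must be < 1 (infinite selectivity)")
    out = R_KJ * T * np.log((1 + de) / (1 - de))
    return float(out) if out.ndim == 0 else out


def ddg_to_de(ddg, temperature_K):
    """Inverse of :func:`de_to_ddg`: de = tanh(ΔΔG / (2·R·T))."""
    ddg = np.asarray(ddg, dtype=float)
    T = np.asarray(temperature_K, dtype=float)
    if np.any(T <= 0):
        raise InvalidArgumentError("temperature must be positive (K)")
    out = np.tanh(ddg / (2 * R_KJ * T))
    return float(out) if out.ndim == 0 else out
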