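"""Survey data model: detection histories, covariates, and screening utilities.

A *site* is the spatial sampling unit (here, a 2-km stretch of trail) and an
*occasion* is one repeat visit within the closed season (here, each of the two
consecutive 1-km halves).  Detection histories are stored per species as
``(n_sites, n_occasions)`` float arrays with values 0, 1 or NaN (missing).
Site covariates live in a :class:`pandas.DataFrame` with one row per site;
occasion covariates are ``(n_sites, n_occasions)`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DetectionDataset",
    "CovariateSpec",
    "SchemaError",
    "ValidationError",
    "load_detection_data",
    "standardize_covariates",
    "collinearity_screen",
    "make_recapture_covariate",
    "add_recapture_covariates",
]


class SchemaError(ValueError):
    """A required column is missing or the file layout is not understood."""


class ValidationError(ValueError):
    """Cell-level contents violate the data contract (e.g. detection not 0/1/NA)."""


@dataclass
class DetectionDataset:
    """Detection/non-detection histories plus covariates for one survey area set.

    Parameters
    ----------
    site_id
        One label per site.
    area
        Categorical area label per site (e.g. ``"Kruger"`` / ``"Limpopo"``).
    histories
        Mapping species name -> ``(n_sites, n_occasions)`` array of
        ``{0.0, 1.0, nan}``.
    site_covariates
        One row per site; numeric columns only after validation.
    occasion_covariates
        Mapping name -> ``(n_sites, n_occasions)`` numeric array
        (e.g. substrate quality in {1,2,3}, previous-detection indicator).
    standardization
        ``name -> (mean, sd)`` recorded by :func:`standardize_covariates` so
        prediction grids can be mapped between raw and z scales.
    """

    site_id: np.ndarray
    area: np.ndarray
    histories: dict[str, np.ndarray]
    site_covariates: pd.DataFrame
    occasion_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.site_id = np.asarray(self.site_id)
        self.area = np.asarray(self.area)
        if not self.histories:
            raise ValidationError("at least one species history is required")
        n = len(self.site_id)
        if len(self.area) != n:
            raise ValidationError("area must have one label per site")
        k = None
        for sp, h in self.histories.items():
            h = np.asarray(h, dtype=float)
            self.histories[sp] = h
            if h.ndim != 2 or h.shape[0] != n:
                raise ValidationError(f"history for {sp!r} must be (n_sites, n_occasions)")
            if k is None:
                k = h.shape[1]
            elif h.shape[1] != k:
                raise ValidationError("all species histories must share n_occasions")
            bad = np.flatnonzero(~(np.isnan(h) | (h == 0) | (h == 1)).all(axis=1))
            if bad.size:
                raise ValidationError(
                    f"history for {sp!r} has values outside {{0,1,NA}} at site rows {bad.tolist()}"
                )
        if k is None or k < 1:
            raise ValidationError("n_occasions must be >= 1")
        if len(self.site_covariates) != n:
            raise ValidationError("site_covariates must have one row per site")
        for name in self.site_covariates.columns:
            col = self.site_covariates[name]
            if col.isna().any():
                raise ValidationError(f"site covariate {name!r} contains NA after validation")
        for name, v in self.occasion_covariates.items():
            v = np.asarray(v, dtype=float)
            self.occasion_covariates[name] = v
            if v.shape != (n, k):
                raise ValidationError(f"occasion covariate {name!r} must be (n_sites, n_occasions)")
            if np.isnan(v).any():
                raise ValidationError(f"occasion covariate {name!r} contains NA")

    @property
    def n_sites(self) -> int:
        return len(self.site_id)

    @property
    def n_occasions(self) -> int:
        return next(iter(self.histories.values())).shape[1]

    @property
    def species(self) -> list[str]:
        return list(self.histories)

    def subset(self, mask: np.ndarray) -> "DetectionDataset":
        """Row-subset (e.g. one survey area); covariate standardization is kept."""
        mask = np.asarray(mask)
        return DetectionDataset(
            site_id=self.site_id[mask],
            area=self.area[mask],
            histories={sp: h[mask] for sp, h in self.histories.items()},
            site_covariates=self.site_covariates.loc[mask].reset_index(drop=True),
            occasion_covariates={nm: v[mask] for nm, v in self.occasion_covariates.items()},
            standardization=dict(self.standardization),
        )

    def copy(self) -> "DetectionDataset":
        return DetectionDataset(
            site_id=self.site_id.copy(),
            area=self.area.copy(),
            histories={sp: h.copy() for sp, h in self.histories.items()},
            site_covariates=self.site_covariates.copy(),
            occasion_covariates={nm: v.copy() for nm, v in self.occasion_covariates.items()},
            standardization=dict(self.standardization),
        )

    # -- design-matrix helpers used by the likelihood modules -----------------

    def psi_design(self, terms: list[str]) -> np.ndarray:
        """Occupancy design matrix ``(n_sites, 1 + len(terms))`` with intercept."""
        cols = [np.ones(self.n_sites)]
        for t in terms:
            if t not in self.site_covariates.columns:
                raise SchemaError(f"site covariate {t!r} not found")
            cols.append(self.site_covariates[t].to_numpy(dtype=float))
        return np.column_stack(cols)

    def p_design(self, terms: list[str]) -> np.ndarray:
        """Detection design ``(n_sites, n_occasions, 1 + len(terms))``.

        Site covariates are broadcast across occasions; occasion covariates
        vary per visit.
        """
        n, k = self.n_sites, self.n_occasions
        cols = [np.ones((n, k))]
        for t in terms:
            if t in self.occasion_covariates:
                cols.append(self.occasion_covariates[t])
            elif t in self.site_covariates.columns:
                cols.append(np.repeat(self.site_covariates[t].to_numpy(dtype=float)[:, None], k, axis=1))
            else:
                raise SchemaError(f"detection covariate {t!r} not found")
        return np.stack(cols, axis=-1)


@dataclass
class CovariateSpec:
    """Covariate terms for a single-species model; the intercept is implicit."""

    psi_terms: list[str] = field(default_factory=list)
    p_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for terms, nm in ((self.psi_terms, "psi_terms"), (self.p_terms, "p_terms")):
            if len(set(terms)) != len(terms):
                raise ValidationError(f"duplicate covariate names in {nm}")

    def validate(self, dataset: DetectionDataset) -> None:
        for t in self.psi_terms:
            if t not in dataset.site_covariates.columns:
                raise SchemaError(f"psi covariate {t!r} not in dataset")
        for t in self.p_terms:
            if t not in dataset.site_covariates.columns and t not in dataset.occasion_covariates:
                raise SchemaError(f"p covariate {t!r} not in dataset")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _occasion_groups(columns: list[str]) -> dict[str, list[str]]:
    """Group columns named ``<stem>_<k>`` (k = 1..K, complete run) by stem."""
    groups: dict[str, dict[int, str]] = {}
    for c in columns:
        stem, _, suffix = c.rpartition("_")
        if stem and suffix.isdigit():
            groups.setdefault(stem, {})[int(suffix)] = c
    out = {}
    for stem, d in groups.items():
        ks = sorted(d)
        if ks == list(range(1, len(ks) + 1)) and len(ks) >= 1:
            out[stem] = [d[k] for k in ks]
    return out


def load_detection_data(
    path,
    species: list[str],
    site_col: str = "site",
    area_col: str = "area",
) -> DetectionDataset:
    """Read a one-row-per-site survey CSV into a :class:`DetectionDataset`.

    Detection columns are named ``<species>_<occasion>`` with 1-based
    occasions (``lion_1``, ``lion_2``, ...).  Any other complete
    ``<stem>_1..<stem>_K`` column run is read as an occasion covariate;
    remaining numeric columns become site covariates.  Missing detections are
    encoded as empty cells or ``NA``.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    groups = _occasion_groups(list(df.columns))
    for sp in species:
        if sp not in groups:
            raise SchemaError(f"detection columns {sp}_1..{sp}_K not found in {path}")
    k = len(groups[species[0]])
    histories = {}
    for sp in species:
        cols = groups[sp]
        if len(cols) != k:
            raise SchemaError(f"species {sp!r} has {len(cols)} occasions; expected {k}")
        h = df[cols].to_numpy(dtype=float)
        bad = ~(np.isnan(h) | (h == 0) | (h == 1))
        if bad.any():
            cells = [
                f"(row {i}, column {cols[j]}, value {h[i, j]!r})"
                for i, j in zip(*np.nonzero(bad))
            ]
            raise ValidationError("detection values outside {0,1,NA}: " + "; ".join(cells))
        histories[sp] = h

    used = {c for sp in species for c in groups[sp]}
    occ_covs = {}
    for stem, cols in groups.items():
        if stem in species or len(cols) != k:
            continue
        v = df[cols].to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValidationError(f"occasion covariate {stem!r} contains NA")
        occ_covs[stem] = v
        used.update(cols)

    site_id = (
        df[site_col].astype(str).to_numpy()
        if site_col in df.columns
        else np.array([f"site_{i}" for i in range(len(df))])
    )
    area = (
        df[area_col].astype(str).to_numpy()
        if area_col in df.columns
        else np.array(["all"] * len(df))
    )
    drop = used | {site_col, area_col}
    site_covs = df[[c for c in df.columns if c not in drop]].copy()
    site_covs = site_covs.select_dtypes(include=[np.number]).reset_index(drop=True)
    return DetectionDataset(site_id, area, histories, site_covs, occ_covs)


def write_detection_data(dataset: DetectionDataset, path) -> None:
    """Write the standard one-row-per-site CSV (inverse of :func:`load_detection_data`)."""
    df = pd.DataFrame({"site": dataset.site_id, "area": dataset.area})
    for sp, h in dataset.histories.items():
        for k in range(h.shape[1]):
            df[f"{sp}_{k + 1}"] = h[:, k]
    for nm, v in dataset.occasion_covariates.items():
        for k in range(v.shape[1]):
            df[f"{nm}_{k + 1}"] = v[:, k]
    for c in dataset.site_covariates.columns:
        df[c] = dataset.site_covariates[c].to_numpy()
    df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Covariate screening
# ---------------------------------------------------------------------------

def standardize_covariates(dataset: DetectionDataset, names: list[str]) -> DetectionDataset:
    """z-scale the named continuous site covariates to mean 0, sd 1.

    Uses the sample standard deviation (n-1 denominator).  The (mean, sd)
    pair is stored on the returned dataset for back-transforming prediction
    grids.  Already-standardized columns pass through unchanged up to
    floating tolerance (idempotent).
    """
    out = dataset.copy()
    for name in names:
        if name not in out.site_covariates.columns:
            raise SchemaError(f"site covariate {name!r} not found")
        x = out.site_covariates[name].to_numpy(dtype=float)
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValidationError(f"covariate {name!r} has zero variance; cannot z-scale")
        out.site_covariates[name] = (x - mu) / sd
        out.standardization[name] = (mu, sd)
    return out


def collinearity_screen(
    dataset: DetectionDataset,
    names: list[str],
    threshold: float = 0.6,
) -> tuple[list[str], pd.DataFrame]:
    """Pairwise Pearson screen; drop one covariate of each pair with |r| > threshold.

    The covariate appearing *later* in ``names`` is dropped, so the retained
    set is deterministic in the caller's stated priority order.  Returns the
    retained names and the full correlation table.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if len(names) < 2:
        raise ValueError("need at least two covariates to screen")
    if dataset.n_sites < 3:
        raise ValidationError("fewer than 3 sites: correlation screen is degenerate")
    sub = dataset.site_covariates[list(names)]
    corr = sub.corr(method="pearson")
    dropped: set[str] = set()
    for i, a in enumerate(names):
        if a in dropped:
            continue
        for b in names[i + 1:]:
            if b in dropped:
                continue
            if abs(corr.loc[a, b]) > threshold:
                dropped.add(b)
    retained = [n for n in names if n not in dropped]
    return retained, corr


def make_recapture_covariate(history: np.ndarray) -> np.ndarray:
    """Previous-occasion detection indicator ("p recap").

    Occasion 1 is always 0; occasion k > 1 equals the detection (0/1) at
    occasion k-1, with a missing previous occasion treated as no detection.
    Absorbs the serial dependence between consecutive occasions of one site.
    """
    h = np.asarray(history, dtype=float)
    if h.ndim == 1:
        h = h[None, :]
    if h.shape[1] < 2:
        raise ValidationError("recapture covariate needs at least 2 occasions")
    prev = np.nan_to_num(h[:, :-1], nan=0.0)
    out = np.concatenate([np.zeros((h.shape[0], 1)), (prev == 1).astype(float)], axis=1)
    return out if np.asarray(history).ndim == 2 else out[0]


def add_recapture_covariates(dataset: DetectionDataset, species: list[str] | None = None) -> DetectionDataset:
    """Attach ``recap_<species>`` occasion covariates for the given species."""
    out = dataset.copy()
    for sp in species or dataset.species:
        out.occasion_covariates[f"recap_{sp}"] = make_recapture_covariate(dataset.histories[sp])
    return out
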