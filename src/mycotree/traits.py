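"""Trait dissimilarity, quadratic diversity and matched species-pool selection.

Species pools for the two mycorrhizal types are chosen to be maximally
similar in their functional traits, so that mycorrhizal type is not
confounded with other trait differences.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MYCORRHIZAL_TYPES = ("AMF", "EMF")

#: exhaustive pool search is used up to this many candidates per type
EXHAUSTIVE_LIMIT = 12


class TraitTable:
    """Species-by-trait matrix with a mycorrhizal-type label per species.

    Parameters
    ----------
    frame:
        Must contain a ``species`` column (unique labels), a
        ``mycorrhizal_type`` column (``"AMF"`` or ``"EMF"``) and at least one
        further trait column.  Numeric trait values must be finite or missing
        (NaN); non-numeric columns are treated as categorical.  Missing values
        are handled by pairwise deletion in :func:`gower_distance`.
    """

    SPECIES_COL = "species"
    MYCO_COL = "mycorrhizal_type"

    def __init__(self, frame: pd.DataFrame):
        if self.SPECIES_COL not in frame.columns or self.MYCO_COL not in frame.columns:
            raise ValueError(
                f"trait table needs {self.SPECIES_COL!r} and {self.MYCO_COL!r} columns"
            )
        frame = frame.copy()
        frame[self.SPECIES_COL] = frame[self.SPECIES_COL].astype(str)
        if frame[self.SPECIES_COL].duplicated().any():
            dupes = frame[self.SPECIES_COL][frame[self.SPECIES_COL].duplicated()]
            raise ValueError(f"duplicate species ids: {sorted(set(dupes))}")
        unknown = set(frame[self.MYCO_COL]) - set(MYCORRHIZAL_TYPES)
        if unknown:
            raise ValueError(
                f"unknown mycorrhizal_type values {sorted(unknown)}; "
                f"expected one of {MYCORRHIZAL_TYPES}"
            )
        trait_cols = [
            c for c in frame.columns if c not in (self.SPECIES_COL, self.MYCO_COL)
        ]
        if not trait_cols:
            raise ValueError("trait table needs at least one trait column")
        frame = frame.set_index(self.SPECIES_COL)
        traits = frame[trait_cols]
        for col in trait_cols:
            if traits[col].isna().all():
                raise ValueError(f"trait column {col!r} is entirely missing")
            if pd.api.types.is_numeric_dtype(traits[col]):
                vals = traits[col].to_numpy(dtype=float)
                if np.isinf(vals).any():
                    raise ValueError(f"non-finite values in numeric trait {col!r}")
        all_missing = traits.isna().all(axis=1)
        if all_missing.any():
            raise ValueError(
                f"species with no trait values: {list(traits.index[all_missing])}"
            )
        self._frame = frame
        self.trait_columns = trait_cols

    # -- accessors ---------------------------------------------------------
    @property
    def species(self) -> list[str]:
        return list(self._frame.index)

    @property
    def mycorrhizal_type(self) -> pd.Series:
        return self._frame[self.MYCO_COL]

    @property
    def traits(self) -> pd.DataFrame:
        return self._frame[self.trait_columns]

    def species_of_type(self, myco: str) -> list[str]:
        if myco not in MYCORRHIZAL_TYPES:
            raise ValueError(f"unknown mycorrhizal type {myco!r}")
        return list(self._frame.index[self._frame[self.MYCO_COL] == myco])

    def __len__(self) -> int:
        return len(self._frame)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self._frame.reset_index().to_csv(path, index=False)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with entries in [0, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def submatrix(self, rows: list[str], cols: list[str]) -> np.ndarray:
        ri = [self.index_of(r) for r in rows]
        ci = [self.index_of(c) for c in cols]
        return self.values[np.ix_(ri, ci)]


@dataclass(frozen=True)
class SpeciesPools:
    """Two disjoint species pools, one per mycorrhizal type.

    ``objective_value`` is the mean pairwise Gower dissimilarity between the
    two pools (the quantity minimised by :func:`select_pools`); ``amf_q`` and
    ``emf_q`` are Rao's Q of each pool under equal abundances, kept as
    diagnostics.
    """

    amf_pool: tuple[str, ...]
    emf_pool: tuple[str, ...]
    objective_value: float = float("nan")
    amf_q: float = float("nan")
    emf_q: float = float("nan")

    def __post_init__(self):
        if set(self.amf_pool) & set(self.emf_pool):
            raise ValueError("species pools must be disjoint")
        object.__setattr__(self, "amf_pool", tuple(self.amf_pool))
        object.__setattr__(self, "emf_pool", tuple(self.emf_pool))

    @property
    def all_species(self) -> tuple[str, ...]:
        return self.amf_pool + self.emf_pool

    def pool_of(self, myco: str) -> tuple[str, ...]:
        return {"AMF": self.amf_pool, "EMF": self.emf_pool}[myco]

    def type_of(self, species: str) -> str:
        if species in self.amf_pool:
            return "AMF"
        if species in self.emf_pool:
            return "EMF"
        raise KeyError(species)


def gower_distance(table: TraitTable) -> DistanceMatrix:
    """Mixed-type Gower dissimilarity between all species pairs.

    Numeric traits contribute the range-normalised absolute difference,
    categorical traits a 0/1 mismatch; contributions are averaged over traits
    where both species have a value (pairwise deletion).  Numeric traits with
    zero range carry no information and are dropped with a warning.
    """
    if len(table) < 2:
        raise ValueError("need at least two species to compute distances")
    labels = tuple(table.species)
    n = len(labels)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    used_any = False
    for col in table.trait_columns:
        series = table.traits[col]
        if pd.api.types.is_numeric_dtype(series):
            x = series.to_numpy(dtype=float)
            valid = np.isfinite(x)
            rng = np.nanmax(x) - np.nanmin(x) if valid.any() else 0.0
            if rng == 0.0:
                logger.warning(
                    "dropping numeric trait %r: zero range across species", col
                )
                continue
            both = valid[:, None] & valid[None, :]
            diff = np.abs(x[:, None] - x[None, :]) / rng
            num += np.where(both, np.nan_to_num(diff), 0.0)
            den += both
        else:
            vals = series.to_numpy(dtype=object)
            valid = ~pd.isna(vals)
            both = valid[:, None] & valid[None, :]
            mismatch = (vals[:, None] != vals[None, :]).astype(float)
            num += np.where(both, mismatch, 0.0)
            den += both
        used_any = True
    if not used_any:
        logger.warning(
            "all trait columns dropped (zero information); species are "
            "indistinguishable, returning zero distances"
        )
        return DistanceMatrix(labels, np.zeros((n, n)))
    off_diag = ~np.eye(n, dtype=bool)
    if (den[off_diag] == 0).any():
        raise ValueError(
            "some species pairs share no non-missing traits; cannot compute "
            "Gower distance"
        )
    d = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(labels, d)


def rao_q(d: DistanceMatrix, p) -> float:
    """Rao's quadratic entropy Q = sum_ij d_ij * p_i * p_j (full double sum)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) != len(d.labels):
        raise ValueError("abundance vector length must match distance labels")
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"abundances must sum to 1 (got {p.sum()!r})")
    return float(p @ d.values @ p)


def _between_pool_objective(d: np.ndarray, a_idx, e_idx) -> float:
    return float(d[np.ix_(list(a_idx), list(e_idx))].mean())


def select_pools(
    table: TraitTable,
    pool_size: int = 5,
    method: str = "auto",
    seed: int | None = 0,
    n_restarts: int = 50,
) -> SpeciesPools:
    """Pick one pool per mycorrhizal type minimising between-pool dissimilarity.

    Exhaustive enumeration over all subset pairs when each type has at most
    ``EXHAUSTIVE_LIMIT`` candidates (or ``method="exhaustive"``), otherwise a
    seeded random-restart swap search (``method="heuristic"``).  Ties are
    broken by lexicographic species order.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    amf = sorted(table.species_of_type("AMF"))
    emf = sorted(table.species_of_type("EMF"))
    for name, cands in (("AMF", amf), ("EMF", emf)):
        if len(cands) < pool_size:
            raise ValueError(
                f"only {len(cands)} {name} candidates for pool_size={pool_size}"
            )
    dm = gower_distance(table)
    d = dm.values
    a_idx = [dm.index_of(s) for s in amf]
    e_idx = [dm.index_of(s) for s in emf]

    if method not in ("auto", "exhaustive", "heuristic"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = (
            "exhaustive"
            if max(len(amf), len(emf)) <= EXHAUSTIVE_LIMIT
            else "heuristic"
        )

    if method == "exhaustive":
        best = None
        for a_sub in itertools.combinations(range(len(amf)), pool_size):
            for e_sub in itertools.combinations(range(len(emf)), pool_size):
                obj = _between_pool_objective(
                    d, [a_idx[i] for i in a_sub], [e_idx[j] for j in e_sub]
                )
                key = (
                    obj,
                    tuple(amf[i] for i in a_sub),
                    tuple(emf[j] for j in e_sub),
                )
                if best is None or key < best:
                    best = key
        obj, a_pool, e_pool = best
    else:
        rng = np.random.default_rng(seed)
        best = None
        nA, nE = len(amf), len(emf)

        def _objective(a_sub, e_sub):
            return _between_pool_objective(
                d, [a_idx[i] for i in sorted(a_sub)], [e_idx[j] for j in sorted(e_sub)]
            )

        for _ in range(n_restarts):
            a_sub = set(rng.choice(nA, size=pool_size, replace=False).tolist())
            e_sub = set(rng.choice(nE, size=pool_size, replace=False).tolist())
            cur = _objective(a_sub, e_sub)
            improved = True
            while improved:
                improved = False
                for which in ("A", "E"):
                    sub = a_sub if which == "A" else e_sub
                    n_cand = nA if which == "A" else nE
                    for out_i in sorted(sub):
                        for in_i in range(n_cand):
                            if in_i in sub:
                                continue
                            cand = (sub - {out_i}) | {in_i}
                            obj = (
                                _objective(cand, e_sub)
                                if which == "A"
                                else _objective(a_sub, cand)
                            )
                            if obj < cur - 1e-15:
                                sub.clear()
                                sub.update(cand)
                                cur = obj
                                improved = True
            key = (
                cur,
                tuple(amf[i] for i in sorted(a_sub)),
                tuple(emf[j] for j in sorted(e_sub)),
            )
            if best is None or key < best:
                best = key
        obj, a_pool, e_pool = best

    # per-pool Rao Q diagnostics under equal abundances
    def _pool_q(pool):
        idx = [dm.index_of(s) for s in pool]
        sub = d[np.ix_(idx, idx)]
        p = np.full(len(pool), 1.0 / len(pool))
        return float(p @ sub @ p)

    return SpeciesPools(
        amf_pool=tuple(a_pool),
        emf_pool=tuple(e_pool),
        objective_value=obj,
        amf_q=_pool_q(a_pool),
        emf_q=_pool_q(e_pool),
    )
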