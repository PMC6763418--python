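"""Matrix distance, row-order randomization null model, and PCA of
alphabet space.

The agreement between two 20x20 amino-acid distance matrices is measured as
the mean absolute difference over the 380 informative (off-diagonal) cells.
Its null distribution comes from a conservative Mantel-style permutation
scheme: only the *row order* of one matrix is shuffled (columns untouched),
preserving the structured information inside each row, and the distance to
the other, fixed, matrix is recomputed per permutation. Permutations are
drawn uniformly with replacement from the 20! orderings, so the identity
may be drawn; the p-value uses the add-one Monte-Carlo estimator and is
never exactly 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .bigmat import AminoAcidDistanceMatrix, AlphabetSimilarityMatrix, N_INFORMATIVE

_OFFDIAG = ~np.eye(20, dtype=bool)

#: Size of the permutation space of 20 row orderings (20! ~ 2.4e18).
N_ROW_ORDERINGS: int = math.factorial(20)


def _as_array(m) -> np.ndarray:
    if isinstance(m, AminoAcidDistanceMatrix):
        return np.asarray(m.values, dtype=float)
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float)
    return np.asarray(m, dtype=float)


def matrix_distance(a, b) -> float:
    """Mean absolute cellwise difference over the 380 informative positions."""
    ma, mb = _as_array(a), _as_array(b)
    if ma.shape != (20, 20) or mb.shape != (20, 20):
        raise ValueError("matrices must be 20x20 over the canonical residue order")
    return float(np.abs(ma - mb)[_OFFDIAG].sum() / N_INFORMATIVE)


def row_randomize(m, permutation) -> np.ndarray:
    """Reorder the rows of *m* by *permutation*; columns are untouched.

    The output is generally asymmetric — that is the point of the null
    model, which permutes one axis only.
    """
    arr = _as_array(m)
    perm = np.asarray(permutation)
    if sorted(perm.tolist()) != list(range(arr.shape[0])):
        raise ValueError("permutation must be a bijection of row indices")
    return arr[perm, :]


@dataclass
class RandomizationReport:
    """Observed matrix distance against its row-permutation null."""

    observed: float
    null_mean: float
    null_min: float
    null_max: float
    p_value: float
    n: int
    seed: int
    mode: str

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def null_distances(
    fixed, shuffled, n: int, seed: int, *, chunk: int = 20_000
) -> np.ndarray:
    """The *n* null matrix distances: distance(fixed, row-permuted shuffled).

    Informative positions remain the 380 off-diagonal grid cells of the
    fixed matrix, even though a row permutation moves cells across the
    diagonal grid. Vectorized in chunks; deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fa, sa = _as_array(fixed), _as_array(shuffled)
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    done = 0
    while done < n:
        b = min(chunk, n - done)
        perms = np.argsort(rng.random((b, 20)), axis=1)  # uniform over 20!
        diffs = np.abs(fa[None, :, :] - sa[perms, :])    # (b, 20, 20)
        out[done : done + b] = diffs[:, _OFFDIAG].sum(axis=1) / N_INFORMATIVE
        done += b
    return out


def randomization_test(
    fixed, shuffled, n: int, seed: int, *, mode: str = "rows-of-second"
) -> tuple[RandomizationReport, np.ndarray]:
    """Observed distance plus an *n*-sample row-permutation null.

    ``p_value = (1 + #{null samples <= observed}) / (n + 1)``: the fraction
    of random row orderings that bring the shuffled matrix at least as close
    to the fixed one as its real row order does.
    """
    samples = null_distances(fixed, shuffled, n, seed)
    observed = matrix_distance(fixed, shuffled)
    p = (1 + int((samples <= observed).sum())) / (n + 1)
    report = RandomizationReport(
        observed=observed,
        null_mean=float(samples.mean()),
        null_min=float(samples.min()),
        null_max=float(samples.max()),
        p_value=p,
        n=n,
        seed=seed,
        mode=mode,
    )
    return report, samples


@dataclass
class PCAResult:
    """Principal components of the alphabet-similarity matrix.

    Rows of the similarity matrix are the observations (one per alphabet),
    columns the features; columns are mean-centered, not scaled.
    ``variance_fractions`` are the per-component shares of total variance
    (descending, summing to 1); ``scores`` the per-alphabet coordinates.
    """

    variance_fractions: np.ndarray
    scores: pd.DataFrame
    total_variance: float

    @property
    def degenerate(self) -> bool:
        """True when the rows were all identical (zero total variance)."""
        return self.total_variance == 0.0

    def top_k_fraction(self, k: int) -> float:
        return float(self.variance_fractions[:k].sum())


def pca(s: AlphabetSimilarityMatrix | pd.DataFrame) -> PCAResult:
    """PCA of an n x n alphabet-similarity matrix (n >= 3 alphabets)."""
    if isinstance(s, AlphabetSimilarityMatrix):
        frame = s.to_frame()
    else:
        frame = s
    x = frame.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 3 or x.shape[1] != n:
        raise ValueError("need a square similarity matrix over >= 3 alphabets")
    centered = x - x.mean(axis=0, keepdims=True)
    total_var = float((centered ** 2).sum() / (n - 1))
    if total_var == 0.0:
        # identical rows: no variance to decompose; report the degenerate
        # case distinctly instead of dividing by zero
        k = n - 1
        return PCAResult(
            variance_fractions=np.zeros(k),
            scores=pd.DataFrame(
                np.zeros((n, k)),
                index=frame.index,
                columns=[f"PC{i + 1}" for i in range(k)],
            ),
            total_variance=0.0,
        )
    model = PCA(n_components=min(n - 1, n))
    coords = model.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PCAResult(
        variance_fractions=model.explained_variance_ratio_.copy(),
        scores=pd.DataFrame(coords, index=frame.index, columns=cols),
        total_variance=total_var,
    )
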