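"""Rank-product differential expression with permutation-based q-values.

The statistic: for a two-group design with ``n_t`` treated and ``n_c``
control samples, every treated/control pair gives a per-probe log fold
change.  Within each of the ``K = n_t * n_c`` pairwise comparisons probes
are ranked (rank 1 = most changed in the requested direction, ties
averaged), and the rank product is the geometric mean of a probe's ranks
across comparisons.  Small RP = consistently extreme.

Significance: the null models an exchangeable no-effect probe *inserted
into the observed experiment*.  Within-group residuals (rescaled by
sqrt(n_g / (n_g - 1)) to undo the variance shrinkage of group centering)
are permuted across probes within each sample column, giving synthetic
noise probes whose pairwise comparisons share replicates exactly like
real probes; each synthetic probe's fold changes are then ranked against
the *observed* fold-change columns, so the null probes face the same
competition — including any true-signal block — that a real null probe
faces.  For a probe at rank position *i* (ascending RP), the expected
number of such null RPs at or below its value, divided by *i*, estimates
the proportion of false positives (pfp) among calls up to that probe —
the q-value.  Values are monotonized so threshold sets are nested.

Ranking permuted noise rows within a signal-free permuted matrix instead
(a scheme sometimes used) is badly conservative whenever a sizeable
fraction of probes carries real signal: in the permuted matrix noise rows
can reach rank 1, while in the real data the signal block occupies the
top ranks and shields them from null probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

Q_THRESHOLD = 0.05
DEFAULT_PERMUTATIONS = 100


class DirectionConflictError(RuntimeError):
    """A probe flagged significant in both directions (impossible under the
    rank construction; indicates corrupted inputs)."""


@dataclass
class ExpressionMatrix:
    """Normalized log-scale intensities with control/treated sample labels."""

    values: pd.DataFrame  # probes x samples
    control: list[str]
    treated: list[str]

    def __post_init__(self) -> None:
        missing = [s for s in self.control + self.treated if s not in self.values.columns]
        if missing:
            raise ValueError(f"samples absent from the matrix: {missing}")
        if len(self.control) < 2 or len(self.treated) < 2:
            raise ValueError("need >= 2 samples per group")
        if self.values.isna().any().any():
            raise ValueError("expression matrix must not contain missing values")

    @classmethod
    def from_groups(cls, values: pd.DataFrame, groups: Mapping[str, str]) -> "ExpressionMatrix":
        control = [s for s in values.columns if groups.get(s) == "control"]
        treated = [s for s in values.columns if groups.get(s) == "treated"]
        return cls(values, control, treated)

    @property
    def n_probes(self) -> int:
        return len(self.values)


def _fold_changes(matrix: ExpressionMatrix) -> np.ndarray:
    """(probes, K) pairwise treated-minus-control log fold changes."""
    t = matrix.values[matrix.treated].to_numpy(float)
    c = matrix.values[matrix.control].to_numpy(float)
    return (t[:, :, None] - c[:, None, :]).reshape(len(t), -1)


def _rank_product_from_fc(fc: np.ndarray, direction: str) -> np.ndarray:
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    signed = -fc if direction == "up" else fc
    ranks = rankdata(signed, axis=0, method="average")
    return np.exp(np.log(ranks).mean(axis=1))


def rank_product(matrix: ExpressionMatrix, direction: str) -> pd.Series:
    """Per-probe rank product for the requested direction.

    A probe strictly most changed in every comparison gets RP = 1; an
    all-constant probe simply receives its (worst) average ranks.
    """
    rp = _rank_product_from_fc(_fold_changes(matrix), direction)
    return pd.Series(rp, index=matrix.values.index, name=f"RP_{direction}")


def _group_residuals(matrix: ExpressionMatrix) -> np.ndarray:
    """Within-group residuals, rescaled so their variance matches the noise.

    Group centering with n_g replicates shrinks the residual variance by
    (n_g - 1) / n_g; the sqrt(n_g / (n_g - 1)) factor undoes that, so a
    resampled noise probe has the same spread as a real null probe.
    """
    x = matrix.values[matrix.control + matrix.treated].to_numpy(float).copy()
    n_c = len(matrix.control)
    for sl, n_g in ((np.s_[:, :n_c], n_c), (np.s_[:, n_c:], len(matrix.treated))):
        x[sl] -= x[sl].mean(axis=1, keepdims=True)
        x[sl] *= np.sqrt(n_g / (n_g - 1))
    return x


def _null_rank_products(
    matrix: ExpressionMatrix, direction: str, permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Insertion-null RPs, shape (B, probes).

    Each replicate permutes the rescaled residual columns across probes
    (synthetic exchangeable noise probes whose pairwise comparisons share
    replicates exactly like real probes), computes their fold changes, and
    ranks them against the observed fold-change columns — the competition
    a real null probe actually faces.
    """
    fc = _fold_changes(matrix)
    signed_obs = -fc if direction == "up" else fc
    sorted_obs = np.sort(signed_obs, axis=0)
    resid = _group_residuals(matrix)
    n_probes = resid.shape[0]
    n_c = len(matrix.control)
    out = np.empty((permutations, n_probes))
    for b in range(permutations):
        perm = np.argsort(rng.random(resid.shape), axis=0)
        xp = np.take_along_axis(resid, perm, axis=0)
        fcp = (xp[:, n_c:, None] - xp[:, None, :n_c]).reshape(n_probes, -1)
        sp = -fcp if direction == "up" else fcp
        ranks = np.empty_like(sp)
        for k in range(sp.shape[1]):
            ranks[:, k] = np.searchsorted(sorted_obs[:, k], sp[:, k], side="left") + 1
        out[b] = np.exp(np.log(ranks).mean(axis=1))
    return out


def estimate_q(
    matrix: ExpressionMatrix,
    rp: pd.Series,
    direction: str,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: Optional[int] = None,
) -> pd.Series:
    """Permutation pfp (q-value) per probe for the given RP values.

    The null permutes each sample column across probes
    (see :func:`_null_rank_products`); q(probe at ascending-RP position i)
    = E[null RP <= rp_i] / i, with a running maximum so q never decreases
    as RP grows.  Values can exceed 1; they are reported as computed here
    and clipped to [0, 1] in the DE table.
    """
    if permutations < 20:
        raise ValueError("at least 20 permutations are required; the estimate is too coarse below that")
    rng = np.random.default_rng(seed)
    null = _null_rank_products(matrix, direction, permutations, rng)
    null_sorted = np.sort(null.ravel())
    order = np.argsort(rp.to_numpy(), kind="stable")
    sorted_rp = rp.to_numpy()[order]
    expected = np.searchsorted(null_sorted, sorted_rp, side="right") / permutations
    pfp = expected / np.arange(1, len(sorted_rp) + 1)
    pfp = np.maximum.accumulate(pfp)
    q = np.empty_like(pfp)
    q[order] = pfp
    return pd.Series(q, index=rp.index, name=f"q_{direction}")


def de_table(
    matrix: ExpressionMatrix,
    permutations: int = DEFAULT_PERMUTATIONS,
    seed: Optional[int] = None,
    threshold: float = Q_THRESHOLD,
    probe_to_gene: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Full DE table: RP and q per direction, winning direction, gene, flag.

    ``probe_to_gene`` defaults to the identity mapping.  The per-probe
    direction is the one with the smaller q (ties -> smaller RP).
    """
    rng = np.random.default_rng(seed)
    fc = _fold_changes(matrix)
    rp_up = pd.Series(_rank_product_from_fc(fc, "up"), index=matrix.values.index)
    rp_down = pd.Series(_rank_product_from_fc(fc, "down"), index=matrix.values.index)
    q_up = estimate_q(matrix, rp_up, "up", permutations, seed=int(rng.integers(0, 2**31 - 1)))
    q_down = estimate_q(matrix, rp_down, "down", permutations, seed=int(rng.integers(0, 2**31 - 1)))
    up_better = (q_up.to_numpy() < q_down.to_numpy()) | (
        (q_up.to_numpy() == q_down.to_numpy()) & (rp_up.to_numpy() <= rp_down.to_numpy())
    )
    direction = np.where(up_better, "up", "down")
    q_best = np.where(up_better, q_up.to_numpy(), q_down.to_numpy())
    probes = list(matrix.values.index)
    genes = [probe_to_gene.get(p, p) if probe_to_gene else p for p in probes]
    table = pd.DataFrame(
        {
            "probe": probes,
            "gene": genes,
            "direction": direction,
            "RP_up": rp_up.to_numpy(),
            "RP_down": rp_down.to_numpy(),
            "q_up": np.clip(q_up.to_numpy(), 0.0, 1.0),
            "q_down": np.clip(q_down.to_numpy(), 0.0, 1.0),
            "q": np.clip(q_best, 0.0, 1.0),
        }
    )
    table["significant"] = table["q"] <= threshold
    return table


def call_de(
    table: pd.DataFrame, threshold: float = Q_THRESHOLD
) -> tuple[set[str], set[str]]:
    """Collapse a DE table to disjoint up/down gene sets at ``q <= threshold``.

    The probe -> gene collapse keeps each gene's best q.  A probe
    significant in both directions raises an internal consistency error.
    """
    both = (table["q_up"] <= threshold) & (table["q_down"] <= threshold)
    if bool(both.any()):
        bad = table.loc[both, "probe"].tolist()[:5]
        raise DirectionConflictError(
            f"probes significant in both directions (first few: {bad})"
        )
    hits = table[table["q"] <= threshold]
    best = hits.sort_values("q", kind="stable").drop_duplicates("gene", keep="first")
    up = set(best.loc[best["direction"] == "up", "gene"])
    down = set(best.loc[best["direction"] == "down", "gene"])
    return up, down
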