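"""Phylogenetic signal statistics for continuous and binary traits.

Two statistics are implemented:

* **Blomberg's K** for continuous traits.  K compares the observed ratio of
  the tip variance around the phylogenetically corrected mean (MSE0) to the
  phylogenetically weighted error (MSE) against the ratio expected under
  Brownian motion on the same tree.  K = 1 matches the Brownian expectation;
  K near 0 means no signal; K > 1 means stronger-than-Brownian conservation.
  Significance comes from shuffling trait values across tips: smaller MSE
  than the permutation null indicates signal.

* **Fritz-Purvis D** for binary traits.  The observed sum of sister-clade
  differences ``d_obs`` (nodal estimates from a tips-to-root pass of
  equal-weight daughter averaging; branch lengths are ignored in this pass)
  is scaled between the mean d of a tip-shuffle null (D = 1, no signal) and
  the mean d of a Brownian-threshold null matched to the observed prevalence
  (D = 0, Brownian-like clumping).  For comparability with K the transform
  ``-D + 1`` is reported alongside: 0 means no signal, larger means more
  conserved.

Both statistics accept trees with polytomies; D resolves them internally
into a deterministic left-to-right ladder of zero-length branches, since
sister-clade differences require bifurcations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .phylo import Phylogeny, TipTraitMap, prune_join, vcv_matrix

__all__ = [
    "ContinuousSignalResult",
    "BinarySignalResult",
    "blomberg_k",
    "estimate_d",
    "transform_d",
    "simulate_bm",
    "threshold_binarize",
    "signal_table",
]


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class ContinuousSignalResult:
    """Blomberg's K with its tip-permutation p-value."""

    K: float
    p_perm: float
    n_perm: int
    n_tips: int
    trait: str = "trait"


@dataclass
class BinarySignalResult:
    """Fritz-Purvis D with both null summaries and the -D+1 transform."""

    D: float
    minus_d_plus_1: float
    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    p_random: float
    p_brownian: float
    n_sims: int
    n_tips: int
    prevalence: float
    trait: str = "trait"
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tree -> array helpers (vectorized cores)
# ---------------------------------------------------------------------------

def _as_values(x) -> Mapping[str, float]:
    return x.values if isinstance(x, TipTraitMap) else dict(x)


def _preorder_arrays(t: Phylogeny):
    """Preorder node list with parent indices and branch lengths.

    Tips are addressable through ``tip_rows``: ``tip_rows[i]`` is the node
    index of ``t.tip_labels[i]``.
    """
    nodes = list(t.tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = np.empty(len(nodes), dtype=np.int64)
    blen = np.zeros(len(nodes))
    label_to_row = {}
    for i, n in enumerate(nodes):
        parent[i] = index[id(n.parent_node)] if n.parent_node is not None else -1
        if n.parent_node is not None:
            blen[i] = n.edge.length
        if n.is_leaf():
            label_to_row[n.taxon.label] = i
    tip_rows = np.array([label_to_row[l] for l in t.tip_labels], dtype=np.int64)
    return parent, blen, tip_rows


def _bm_tip_matrix(
    parent: np.ndarray,
    blen: np.ndarray,
    tip_rows: np.ndarray,
    sigma2: float,
    rng: np.random.Generator,
    n_reps: int,
) -> np.ndarray:
    """Simulate Brownian motion; returns (n_tips, n_reps) tip values."""
    n_nodes = parent.size
    vals = np.empty((n_nodes, n_reps))
    incr = rng.standard_normal((n_nodes, n_reps))
    incr *= np.sqrt(sigma2 * blen)[:, None]
    vals[0] = 0.0  # preorder: node 0 is the root
    for i in range(1, n_nodes):
        vals[i] = vals[parent[i]] + incr[i]
    return vals[tip_rows]


def _ladder_arrays(t: Phylogeny):
    """Left/right child indices of a bifurcating version of ``t``.

    Polytomies are resolved into a left-to-right ladder (children beyond the
    first are combined pairwise, in tree order, via zero-length internal
    branches).  Returned indices are postorder over internal nodes; indices
    below ``n_tips`` refer to tips in :attr:`Phylogeny.tip_labels` order.
    """
    labels = t.tip_labels
    tip_idx = {l: i for i, l in enumerate(labels)}
    n_tips = len(labels)
    left: list[int] = []
    right: list[int] = []
    counter = [n_tips]

    def visit(node) -> int:
        if node.is_leaf():
            return tip_idx[node.taxon.label]
        kids = [visit(c) for c in node.child_nodes()]
        if len(kids) == 1:  # unifurcation: pass through
            return kids[0]
        acc = kids[0]
        for k in kids[1:]:
            left.append(acc)
            right.append(k)
            acc = counter[0]
            counter[0] += 1
        return acc

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * t.n_tips + 100))
    try:
        visit(t.tree.seed_node)
    finally:
        sys.setrecursionlimit(old)
    return (
        n_tips,
        np.asarray(left, dtype=np.int64),
        np.asarray(right, dtype=np.int64),
    )


def _d_values(n_tips: int, left: np.ndarray, right: np.ndarray,
              X: np.ndarray) -> np.ndarray:
    """Sum of sister-clade differences for each column of X (n_tips x m)."""
    m = X.shape[1]
    est = np.empty((n_tips + left.size, m))
    est[:n_tips] = X
    d = np.zeros(m)
    for i in range(left.size):
        a = est[left[i]]
        b = est[right[i]]
        d += np.abs(a - b)
        est[n_tips + i] = 0.5 * (a + b)
    return d


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

def _k_mse(W: np.ndarray, ones_W: np.ndarray, sum_W: float,
           X: np.ndarray) -> np.ndarray:
    """Phylogenetic MSE of each column of X around its GLS mean."""
    n = X.shape[0]
    ahat = (ones_W @ X) / sum_W
    Dev = X - ahat
    return np.einsum("ij,ij->j", Dev, W @ Dev) / (n - 1)


def blomberg_k(
    t: Phylogeny,
    x,
    n_perm: int = 1000,
    seed: int | None = None,
    trait: str | None = None,
) -> ContinuousSignalResult:
    """Blomberg's K with a tip-permutation test.

    The GLS quantities use V from :func:`vcv_matrix`:

    - phylogenetic mean  a = (1' V^-1 x) / (1' V^-1 1)
    - MSE0 = (x - a)'(x - a) / (n - 1)
    - MSE  = (x - a)' V^-1 (x - a) / (n - 1)
    - E[MSE0/MSE] under BM = (tr V - n / (1' V^-1 1)) / (n - 1)
    - K = (MSE0 / MSE) / E[MSE0/MSE]

    The permutation p-value counts tip shuffles whose MSE is at most the
    observed one (smaller MSE = stronger signal) with the add-one
    convention p = (1 + r) / (n_perm + 1).  ``n_perm=0`` skips the test
    (p reported as NaN).
    """
    values = _as_values(x)
    if not set(t.tip_labels) <= set(values):
        t, xm = prune_join(t, values)
        values = xm.values
    labels = t.tip_labels
    xv = np.array([float(values[l]) for l in labels])
    n = xv.size
    if n < 3:
        raise ValueError("Blomberg's K needs at least 3 tips")
    if np.ptp(xv) == 0:
        raise ValueError("trait is constant across tips; K undefined")

    V = vcv_matrix(t).to_numpy()
    try:
        cho = linalg.cho_factor(V)
        W = linalg.cho_solve(cho, np.eye(n))
    except linalg.LinAlgError:
        warnings.warn(
            "singular phylogenetic covariance matrix; using pseudoinverse",
            stacklevel=2,
        )
        W = np.linalg.pinv(V, rcond=1e-10)
    ones = np.ones(n)
    ones_W = ones @ W
    sum_W = float(ones_W @ ones)

    ahat = float(ones_W @ xv) / sum_W
    dev = xv - ahat
    mse0 = float(dev @ dev) / (n - 1)
    mse = float(dev @ (W @ dev)) / (n - 1)
    expected = (np.trace(V) - n / sum_W) / (n - 1)
    K = (mse0 / mse) / expected

    if n_perm > 0:
        rng = np.random.default_rng(seed)
        perms = np.empty((n, n_perm))
        for j in range(n_perm):
            perms[:, j] = rng.permutation(xv)
        mse_null = _k_mse(W, ones_W, sum_W, perms)
        r = int(np.sum(mse_null <= mse + 1e-12))
        p = (1 + r) / (n_perm + 1)
    else:
        p = float("nan")
    name = trait or (x.name if isinstance(x, TipTraitMap) else "trait")
    return ContinuousSignalResult(
        K=float(K), p_perm=float(p), n_perm=n_perm, n_tips=n, trait=name
    )


# ---------------------------------------------------------------------------
# Brownian simulation and thresholding
# ---------------------------------------------------------------------------

def simulate_bm(
    t: Phylogeny, sigma2: float = 1.0, seed=None, name: str = "bm"
) -> TipTraitMap:
    """Brownian motion on the tree: root value 0, each branch adds an
    independent Normal(0, sigma2 * branch_length) increment."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    parent, blen, tip_rows = _preorder_arrays(t)
    tips = _bm_tip_matrix(parent, blen, tip_rows, sigma2, rng, 1)[:, 0]
    return TipTraitMap(
        values=dict(zip(t.tip_labels, map(float, tips))),
        name=name,
        kind="continuous",
    )


def threshold_binarize(values: Mapping[str, float], k_ones: int,
                       name: str = "thresholded") -> TipTraitMap:
    """Set the ``k_ones`` largest values to 1 and the rest to 0.

    Ties at the cutoff are broken by tip-label order, so the output is a
    deterministic function of its input.
    """
    values = _as_values(values)
    labels = sorted(values)
    n = len(labels)
    if not 0 < k_ones < n:
        raise ValueError(f"k_ones must be in (0, {n}); got {k_ones}")
    order = sorted(range(n), key=lambda i: (-values[labels[i]], labels[i]))
    out = {l: 0.0 for l in labels}
    for i in order[:k_ones]:
        out[labels[i]] = 1.0
    return TipTraitMap(values=out, name=name, kind="binary")


def _threshold_columns(X: np.ndarray, k_ones: int) -> np.ndarray:
    """Column-wise rank thresholding of (n, m) to exactly k_ones ones."""
    n, m = X.shape
    # ties have measure zero for BM draws; argsort descending suffices
    order = np.argsort(-X, axis=0, kind="stable")
    out = np.zeros_like(X)
    cols = np.arange(m)
    for r in range(k_ones):
        out[order[r], cols] = 1.0
    return out


# ---------------------------------------------------------------------------
# Fritz-Purvis D
# ---------------------------------------------------------------------------

def estimate_d(
    t: Phylogeny,
    x,
    n_sims: int = 1000,
    seed: int | None = None,
    trait: str | None = None,
) -> BinarySignalResult:
    """Fritz-Purvis D for a binary trait, with shuffle and Brownian nulls.

    ``d_obs`` sums |est(left) - est(right)| over internal nodes, where nodal
    estimates are equal-weight daughter averages computed tips-to-root
    (branch lengths ignored in this pass).  The Brownian null simulates BM
    on the same tree (branch lengths used) and rank-thresholds every
    replicate to the observed number of 1-tips.  D scales d_obs between the
    two null means; p-values are the fractions of null replicates with
    d <= d_obs (small d = clumped = signal).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    values = _as_values(x)
    if not set(t.tip_labels) <= set(values):
        t, xm = prune_join(t, values)
        values = xm.values
    labels = t.tip_labels
    xv = np.array([float(values[l]) for l in labels])
    if not set(np.unique(xv)) <= {0.0, 1.0}:
        raise ValueError("trait must be binary (0/1)")
    k_ones = int(xv.sum())
    n = xv.size
    if k_ones in (0, n):
        raise ValueError("both states must be present among the tips")

    n_tips, left, right = _ladder_arrays(t)
    d_obs = float(_d_values(n_tips, left, right, xv[:, None])[0])

    rng = np.random.default_rng(seed)

    shuffles = np.empty((n, n_sims))
    for j in range(n_sims):
        shuffles[:, j] = rng.permutation(xv)
    d_rand = _d_values(n_tips, left, right, shuffles)

    parent, blen, tip_rows = _preorder_arrays(t)
    bm_tips = _bm_tip_matrix(parent, blen, tip_rows, 1.0, rng, n_sims)
    bm_bin = _threshold_columns(bm_tips, k_ones)
    d_brown = _d_values(n_tips, left, right, bm_bin)

    mean_rand = float(d_rand.mean())
    mean_brown = float(d_brown.mean())
    denom = mean_rand - mean_brown
    if denom == 0:
        raise ValueError(
            "degenerate normalization: shuffle and Brownian null means are "
            f"equal ({mean_rand}); d_obs={d_obs}, n={n}, k_ones={k_ones}"
        )
    D = (d_obs - mean_brown) / denom
    name = trait or (x.name if isinstance(x, TipTraitMap) else "trait")
    return BinarySignalResult(
        D=float(D),
        minus_d_plus_1=transform_d(D),
        d_obs=d_obs,
        mean_d_random=mean_rand,
        mean_d_brownian=mean_brown,
        p_random=float(np.mean(d_rand <= d_obs)),
        p_brownian=float(np.mean(d_brown <= d_obs)),
        n_sims=n_sims,
        n_tips=n,
        prevalence=k_ones / n,
        trait=name,
        meta={
            "nodal_pass": "equal-weight daughter averaging, branch lengths ignored",
            "polytomies": "resolved left-to-right with zero-length branches",
        },
    )


def transform_d(D: float) -> float:
    """Map D onto the K-like scale: -D + 1 (0 = no signal, >0 = conserved)."""
    return -float(D) + 1.0


# ---------------------------------------------------------------------------
# trait table driver
# ---------------------------------------------------------------------------

def signal_table(
    tree: Phylogeny,
    traits: Sequence[TipTraitMap],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-trait signal summary: K for continuous traits, -D+1 for binary.

    One row per trait with the statistic, the tip-permutation p-value, the
    number of tips used, and a significance flag at ``alpha``.  Traits whose
    preconditions fail (constant values, single state, too few shared tips)
    get a row carrying the error note instead of being dropped silently.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for trait_map, child in zip(traits, ss.spawn(max(len(traits), 1))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        row = {
            "trait": trait_map.name,
            "type": "Categorical" if trait_map.kind == "binary" else "Continuous",
            "statistic": np.nan,
            "p_value": np.nan,
            "n": 0,
            "significant": False,
            "note": "",
        }
        try:
            if trait_map.kind == "binary":
                res = estimate_d(tree, trait_map, n_sims=n_perm, seed=sub_seed)
                row.update(
                    statistic=res.minus_d_plus_1,
                    p_value=res.p_random,
                    n=res.n_tips,
                )
            else:
                resk = blomberg_k(tree, trait_map, n_perm=n_perm, seed=sub_seed)
                row.update(statistic=resk.K, p_value=resk.p_perm, n=resk.n_tips)
            row["significant"] = bool(row["p_value"] < alpha)
        except ValueError as exc:
            row["note"] = str(exc)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["trait", "type", "statistic", "p_value", "n", "significant", "note"],
    )
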