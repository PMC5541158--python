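"""Per-KO logistic-regression screen against environmental optima.

For each KEGG ortholog, the probability that a strain's genome carries it
is modeled as a logistic function of the strain's pH or salinity optimum:

    P(KO present) = expit(beta0 + beta1 * optimum)

A significant slope after Bonferroni correction over the number of fitted
models marks a putative genotype-phenotype link; the slope's sign says
whether the KO is associated with higher (+) or lower (-) optima.
Significant KOs are further classified as transporters by membership in
the Transporter Classification Database (TCDB), since surface transport is
the dominant known mechanism of salinity and pH adaptation.

The logistic fit is a two-parameter Newton (iteratively reweighted least
squares) maximum-likelihood fit; inference on the slope is a two-sided
Wald test by default, with a likelihood-ratio option.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogisticFit",
    "EnrichmentResult",
    "ScreenConfig",
    "bonferroni_threshold",
    "fit_logistic",
    "ko_screen",
    "classify_transporter",
    "annotate_transporters",
    "summarize_screen",
    "load_tcdb",
    "packaged_tcdb",
    "packaged_marker_table",
    "marker_table_results",
]

_KO_RE = re.compile(r"^K\d{5}$")


@dataclass
class LogisticFit:
    beta0: float
    beta1: float
    se1: float
    p_value: float
    converged: bool
    n: int
    separated: bool = False
    n_iter: int = 0
    loglik: float = float("nan")


@dataclass
class EnrichmentResult:
    ko_id: str
    trait: str
    coefficient_sign: Optional[str]  # '+' / '-' / None when untestable
    p_value: float
    significant: bool
    transporter: Optional[bool] = None
    reason: str = ""  # non-empty for untestable/separated KOs
    beta1: float = float("nan")


@dataclass
class ScreenConfig:
    """Screen-wide settings; ``m`` overrides the Bonferroni family size
    (e.g. to apply a cutoff computed for a larger published family)."""

    alpha: float = 0.05
    m: Optional[int] = None
    trait: str = "ph"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise cutoff alpha / m (7.3e-6 for alpha=0.05, m=6889)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    return alpha / m


# ---------------------------------------------------------------------------
# logistic fit
# ---------------------------------------------------------------------------

def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    y,
    x,
    max_iter: int = 100,
    tol: float = 1e-8,
    test: str = "wald",
) -> LogisticFit:
    """Maximum-likelihood logistic regression of a binary response on one
    covariate, by Newton/IRLS.

    Convergence: |change in log-likelihood| < ``tol`` or ``max_iter``
    iterations.  Complete or quasi-complete separation (the slope diverging,
    detected as fitted logits beyond +-30 with a still-improving
    likelihood, or a numerically singular Hessian) yields
    ``converged=False`` with ``separated=True`` and no p-value (NaN).
    ``test`` selects Wald (default) or likelihood-ratio inference on the
    slope.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError("y and x must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("y has a single class; logistic fit undefined")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope not identifiable")
    if test not in ("wald", "lr"):
        raise ValueError("test must be 'wald' or 'lr'")

    n = y.size
    X = np.column_stack([np.ones(n), x])
    pbar = y.mean()
    beta = np.array([np.log(pbar / (1 - pbar)), 0.0])
    eta = X @ beta
    ll = _loglik(y, eta)
    separated = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            separated = True
            break
        # step-halve if the likelihood would decrease
        for _ in range(30):
            cand = beta + step
            eta_c = X @ cand
            ll_c = _loglik(y, eta_c)
            if ll_c >= ll - 1e-12:
                break
            step = step / 2.0
        beta, eta = cand, eta_c
        if np.abs(eta).max() > 30.0 and ll_c - ll > tol:
            separated = True
            ll = ll_c
            break
        delta, ll = ll_c - ll, ll_c
        if abs(delta) < tol:
            converged = True
            break

    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    se1 = float("nan")
    p = float("nan")
    if converged and not separated:
        try:
            cov = np.linalg.inv(H)
            se1 = float(np.sqrt(cov[1, 1]))
        except np.linalg.LinAlgError:
            separated = True
            converged = False
    if converged and not separated:
        if test == "wald":
            z = beta[1] / se1
            p = float(2.0 * stats.norm.sf(abs(z)))
        else:
            ll0 = _loglik(y, np.full(n, np.log(pbar / (1 - pbar))))
            lr = max(2.0 * (ll - ll0), 0.0)
            p = float(stats.chi2.sf(lr, df=1))
    return LogisticFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        se1=se1,
        p_value=p,
        converged=converged and not separated,
        n=n,
        separated=separated,
        n_iter=it,
        loglik=ll,
    )


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def ko_screen(
    mat: pd.DataFrame,
    optima: Mapping[str, float] | pd.Series,
    cfg: ScreenConfig | None = None,
    test: str = "wald",
) -> list[EnrichmentResult]:
    """One logistic model per testable KO against the trait optimum.

    Strains without an optimum are dropped once, before any model is fit
    (listwise, identical for every KO).  A KO is testable when it is
    present in at least one and absent in at least one analyzed strain;
    the Bonferroni family size m is the number of testable KOs (separated
    fits included — they were fitted) unless ``cfg.m`` overrides it.
    A KO is significant iff its fit converged and p < alpha / m.
    Untestable and separated KOs are reported with a reason, never
    silently dropped.
    """
    cfg = cfg or ScreenConfig()
    optima = pd.Series(dict(optima) if not isinstance(optima, pd.Series) else optima)
    optima = optima.dropna()
    strains = mat.index.intersection(optima.index)
    if len(strains) < 2:
        raise ValueError(
            "need at least 2 strains with both a KO profile and an optimum"
        )
    sub = mat.loc[strains]
    x = optima.loc[strains].to_numpy(dtype=float)

    cols = sorted(sub.columns)
    testable, untestable = [], []
    for ko in cols:
        yv = sub[ko].to_numpy(dtype=float)
        if yv.min() == yv.max():
            untestable.append(ko)
        else:
            testable.append((ko, yv))
    if not testable:
        raise ValueError("no testable KOs (every column is constant)")
    m = cfg.m if cfg.m is not None else len(testable)
    cutoff = bonferroni_threshold(cfg.alpha, m)

    results: list[EnrichmentResult] = []
    for ko in untestable:
        results.append(
            EnrichmentResult(
                ko_id=ko, trait=cfg.trait, coefficient_sign=None,
                p_value=float("nan"), significant=False,
                reason="untestable: no presence/absence variation",
            )
        )
    for ko, yv in testable:
        fit = fit_logistic(yv, x, test=test)
        sign = "+" if fit.beta1 > 0 else "-"
        if fit.separated:
            results.append(
                EnrichmentResult(
                    ko_id=ko, trait=cfg.trait, coefficient_sign=sign,
                    p_value=float("nan"), significant=False,
                    reason="separation: slope diverges", beta1=fit.beta1,
                )
            )
        else:
            sig = bool(fit.converged and fit.p_value < cutoff)
            results.append(
                EnrichmentResult(
                    ko_id=ko, trait=cfg.trait, coefficient_sign=sign,
                    p_value=fit.p_value, significant=sig, beta1=fit.beta1,
                    reason="" if fit.converged else "did not converge",
                )
            )
    # internal consistency: the cutoff applied is alpha/m for the reported m
    assert cutoff == bonferroni_threshold(cfg.alpha, m)
    return results


# ---------------------------------------------------------------------------
# transporter classification and summaries
# ---------------------------------------------------------------------------

def classify_transporter(ko_id: str, tcdb: set) -> bool:
    """Closed-world TCDB membership for a KO id of the form K#####."""
    if not _KO_RE.match(str(ko_id)):
        raise ValueError(f"malformed KO id {ko_id!r}")
    return ko_id in tcdb


def annotate_transporters(
    results: Iterable[EnrichmentResult], tcdb: set
) -> list[EnrichmentResult]:
    out = list(results)
    for r in out:
        r.transporter = classify_transporter(r.ko_id, tcdb)
    return out


def summarize_screen(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Per-trait counts of enriched KOs and their transporter share.

    A KO significant for more than one trait counts toward each; the
    transporter percentage is rounded half-up to an integer.
    """
    from .genome_link import percent_round_half_up

    sig = [r for r in results if r.significant]
    traits = sorted({r.trait for r in sig})
    rows = []
    for trait in traits:
        hits = [r for r in sig if r.trait == trait]
        n_tr = sum(1 for r in hits if r.transporter)
        rows.append(
            {
                "trait": trait,
                "n_enriched": len(hits),
                "n_transporter": n_tr,
                "pct_transporter": (
                    percent_round_half_up(n_tr, len(hits)) if hits else 0
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["trait", "n_enriched", "n_transporter", "pct_transporter"]
    )


def results_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Flat per-KO results for writing to delimited text."""
    return pd.DataFrame(
        [
            {
                "ko_id": r.ko_id,
                "trait": r.trait,
                "coefficient_sign": r.coefficient_sign,
                "p_value": r.p_value,
                "significant": r.significant,
                "transporter": r.transporter,
                "reason": r.reason,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# packaged reference data
# ---------------------------------------------------------------------------

def load_tcdb(path) -> set:
    """TCDB membership list, one KO id per line ('#' comments allowed)."""
    out = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.add(s)
    return out


def packaged_tcdb() -> set:
    """The packaged TCDB membership snapshot (covers the packaged marker
    set; KOs outside it are treated as non-transporters)."""
    with resources.as_file(
        resources.files("traitsignal.data") / "tcdb_ko_snapshot.txt"
    ) as p:
        return load_tcdb(p)


def packaged_marker_table() -> pd.DataFrame:
    """The packaged reference table of KO markers reported enriched for pH
    and salinity optima (ko_id, optimum in {pH, Salinity, Both},
    description, coefficient sign, TCDB flag)."""
    with resources.as_file(
        resources.files("traitsignal.data") / "enriched_ko_markers.tsv"
    ) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def marker_table_results(
    table: pd.DataFrame | None = None, tcdb: set | None = None
) -> list[EnrichmentResult]:
    """Expand the marker table into per-trait EnrichmentResults.

    Rows labeled 'Both' yield one result per trait.  Transporter flags come
    from :func:`classify_transporter` against the TCDB snapshot, not from
    the table's own column (the table column is retained for cross-checks).
    """
    table = packaged_marker_table() if table is None else table
    tcdb = packaged_tcdb() if tcdb is None else tcdb
    out = []
    for row in table.itertuples(index=False):
        traits = (
            ["ph", "salinity"]
            if row.optimum == "Both"
            else [row.optimum.lower()]
        )
        for trait in traits:
            out.append(
                EnrichmentResult(
                    ko_id=row.ko_id,
                    trait=trait,
                    coefficient_sign=row.sign,
                    p_value=float("nan"),
                    significant=True,
                    transporter=classify_transporter(row.ko_id, tcdb),
                )
            )
    return out
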