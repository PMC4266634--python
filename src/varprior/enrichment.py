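"""Category over-representation: hypergeometric p-values and Bayes factors.

Given a query gene set, a background universe and a category → members
map, each category is scored two ways:

* an upper-tail hypergeometric p-value, P(X >= k) for overlap k when
  drawing |query| genes without replacement from a universe containing
  |category| members, with Benjamini–Hochberg (default) or Bonferroni
  correction across categories;
* a Bayes factor comparing a one-sided enrichment alternative against
  the background-rate null.  Writing p0 = |category| / |universe| and
  k successes among n = |query| draws, the null is Binomial(n, p0) and
  the alternative integrates the binomial likelihood over
  theta ~ Beta(a, b) truncated to (p0, 1]:

      BF = ∫_{p0}^{1} theta^k (1-theta)^{n-k} dPi(theta)
           ---------------------------------------------
                      p0^k (1-p0)^{n-k}

  The one-sided alternative makes BF monotone in the overlap count
  (every density point theta > p0 has a likelihood ratio increasing in
  k), BF = 1 for an empty query and BF >> 1 when a small category is
  fully contained in the query.  Default prior Beta(1, 1), i.e. uniform
  on the enriched range.

Context-sensitive enrichment (e.g. against genes expressed in one
tissue) is achieved by supplying a restricted background universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import betaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass
class CategoryMap:
    """Category id -> member gene set over a background universe."""

    categories: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self):
        if not self.background:
            raise EnrichmentError("background universe is empty")
        self.categories = {
            cid: frozenset(members) & self.background
            for cid, members in self.categories.items()
        }

    def __len__(self) -> int:
        return len(self.categories)


def read_gmt(path, background: set[str] | None = None) -> CategoryMap:
    """Read GMT (category, description, members...); background defaults
    to the union of all category members."""
    cats: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            cats[parts[0]] = frozenset(g for g in parts[2:] if g)
    if background is None:
        background = set().union(*cats.values()) if cats else set()
    return CategoryMap(cats, frozenset(background))


def _restrict_query(query, background) -> frozenset[str]:
    q = frozenset(query)
    dropped = q - background
    if dropped:
        logger.warning(
            "%d query genes outside the background were dropped: %s",
            len(dropped),
            ", ".join(sorted(dropped)[:5]),
        )
    return q & background


def hypergeometric_enrichment(
    query,
    categories: CategoryMap,
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with multiplicity correction.

    Returns one row per category: overlap, p_value, adjusted_p and
    bayes_factor (uniform enrichment prior), sorted by p.
    """
    q = _restrict_query(query, categories.background)
    big_n = len(categories.background)
    n = len(q)
    rows = []
    for cid, members in categories.categories.items():
        big_k = len(members)
        k = len(q & members)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        bf = bayes_factor(k, n, big_k / big_n)
        rows.append((cid, big_k, k, min(p, 1.0), bf))
    df = pd.DataFrame(
        rows, columns=["category", "size", "overlap", "p_value", "bayes_factor"]
    )
    if len(df):
        _, adj, _, _ = multipletests(df["p_value"].to_numpy(), method=correction)
        df["adjusted_p"] = np.maximum(adj, df["p_value"])
    else:
        df["adjusted_p"] = []
    return df.sort_values(["p_value", "category"]).reset_index(drop=True)[
        ["category", "size", "overlap", "p_value", "adjusted_p", "bayes_factor"]
    ]


def bayes_factor(
    overlap: int, query_size: int, background_rate: float, prior_params=(1.0, 1.0)
) -> float:
    """One-sided enrichment Bayes factor (see module docstring).

    ``prior_params`` (a, b) shape the Beta prior before truncation to
    (p0, 1]; both must be positive.  BF > 1 favours enrichment.
    """
    a, b = prior_params
    if a <= 0 or b <= 0:
        raise EnrichmentError("prior parameters must be positive")
    if not 0.0 <= background_rate <= 1.0:
        raise EnrichmentError("background_rate must lie in [0, 1]")
    k, n, p0 = overlap, query_size, background_rate
    if n == 0:
        return 1.0
    if p0 >= 1.0:
        return 1.0  # category is the whole universe; models coincide
    if p0 <= 0.0:
        return np.inf if k > 0 else 1.0

    def integrand(theta: float) -> float:
        # binomial kernel x prior density, scaled by the null for stability
        log_ratio = (
            k * (np.log(theta) - np.log(p0))
            + (n - k) * (np.log1p(-theta) - np.log1p(-p0))
            + (a - 1) * np.log(theta)
            + (b - 1) * np.log1p(-theta)
        )
        return float(np.exp(log_ratio))

    num, _ = integrate.quad(integrand, p0, 1.0, limit=200)
    prior_mass = float(stats.beta.sf(p0, a, b))  # normalizes the truncation
    if prior_mass <= 0:
        return 1.0
    return num / (float(np.exp(betaln(a, b))) * prior_mass)


def bayes_factor_enrichment(
    query, categories: CategoryMap, prior_params=(1.0, 1.0)
) -> pd.DataFrame:
    """Per-category Bayes factors for the one-sided enrichment model."""
    q = _restrict_query(query, categories.background)
    big_n = len(categories.background)
    rows = []
    for cid, members in categories.categories.items():
        k = len(q & members)
        bf = bayes_factor(k, len(q), len(members) / big_n, prior_params)
        rows.append((cid, len(members), k, bf))
    return pd.DataFrame(
        rows, columns=["category", "size", "overlap", "bayes_factor"]
    ).sort_values("category").reset_index(drop=True)
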