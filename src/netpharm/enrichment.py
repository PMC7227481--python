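"""Hypergeometric over-representation analysis against GMT gene-set collections.

Given a query gene set (e.g. screened core targets) and an annotation
collection (GO terms, pathways, tissues) in GMT format, each term is tested
for over-representation with the hypergeometric upper tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n)

where N is the background universe size, K the term size, n the number of
query genes inside the universe, and k the query∩term overlap.  The
significance call follows the conventional raw p < alpha (default 0.05);
Benjamini–Hochberg adjusted values are always reported alongside so the
multiple-testing question stays visible.  The default universe is the union
of all term members (annotation-based background); a user-supplied
background overrides it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netcore import ParseError, normalize_symbol
from .target_assembly import TargetSet

RESULT_COLUMNS = (
    "term", "description", "k", "K", "n", "N", "fold", "p", "p_adj", "significant",
)


@dataclass
class AnnotationDB:
    """Term → (description, member set) plus a background universe.

    Invariant: every term's members are a subset of the universe (the loader
    either extends the universe by union or trims members to it).
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def members(self, term: str) -> frozenset[str]:
        return self.terms[term][1]


def read_gmt(
    path: str | Path,
    universe: Iterable[str] | None = None,
    trim_to_universe: bool = False,
) -> AnnotationDB:
    """Read a GMT collection (term, description, member genes...).

    Duplicate genes within a line are deduplicated.  With no explicit
    ``universe`` the background is the union of all member sets.  With one,
    terms are either trimmed to it (``trim_to_universe``) or the universe is
    extended by union (default) to preserve the subset invariant.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields "
                    f"(term, description, genes...), got {len(fields)}"
                )
            term, desc = fields[0].strip(), fields[1].strip()
            genes = frozenset(
                normalize_symbol(g) for g in fields[2:] if g.strip()
            )
            if not genes:
                raise ParseError(f"{path}:{lineno}: term {term!r} has no member genes")
            terms[term] = (desc, genes)
    member_union = frozenset().union(*(m for _, m in terms.values())) if terms else frozenset()
    if universe is None:
        uni = member_union
    else:
        uni = frozenset(normalize_symbol(g) for g in universe)
        if trim_to_universe:
            terms = {
                t: (d, m & uni) for t, (d, m) in terms.items() if m & uni
            }
        else:
            uni = uni | member_union
    return AnnotationDB(terms=terms, universe=uni)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Evaluated through the survival function, whose terms are accumulated in
    log space, so it stays accurate deep in the tail.  P(X >= 0) = 1 and
    k > min(K, n) gives 0 exactly.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got N={N}, K={K}, n={n}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k == 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in p_adj]


@dataclass
class EnrichmentResult:
    """Per-term overlap counts, hypergeometric p, and BH-adjusted p.

    ``frame`` columns: term, description, k, K, n, N, fold, p, p_adj,
    significant — sorted by raw p ascending (term ID breaks ties).
    """

    frame: pd.DataFrame
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.frame["significant"].sum())

    def top_terms(self, n: int = 10) -> list[str]:
        return list(self.frame["term"].head(n))

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def bubble_chart_frame(self) -> pd.DataFrame:
        """(term, fold, −log10 p, k) rows for bubble-chart plotting."""
        out = pd.DataFrame(
            {
                "term": self.frame["term"],
                "fold": self.frame["fold"],
                "neg_log10_p": -np.log10(self.frame["p"]),
                "k": self.frame["k"],
            }
        )
        return out

    def write_bubble_tsv(self, path: str | Path) -> None:
        self.bubble_chart_frame().to_csv(path, sep="\t", index=False)


def enrich(
    query: TargetSet,
    db: AnnotationDB,
    alpha: float = 0.05,
    min_overlap: int = 1,
) -> EnrichmentResult:
    """Over-representation of ``query`` in every term of ``db``.

    Only query genes inside the universe count toward n; terms with overlap
    below ``min_overlap`` are omitted.  Raises if the query is disjoint from
    the universe.
    """
    q = query.members & db.universe
    if not q:
        raise ValueError(
            f"query {query.label!r} shares no genes with the annotation universe "
            f"({len(db.universe)} genes)"
        )
    N, n = len(db.universe), len(q)
    rows = []
    for term, (desc, members) in db.terms.items():
        k = len(q & members)
        if k < min_overlap:
            continue
        K = len(members)
        p = hypergeom_upper_tail(N, K, n, k)
        fold = (k / n) / (K / N)
        rows.append((term, desc, k, K, n, N, fold, p))
    frame = pd.DataFrame(
        rows, columns=["term", "description", "k", "K", "n", "N", "fold", "p"]
    )
    if len(frame):
        frame["p_adj"] = bh_adjust(frame["p"].tolist())
        frame["significant"] = frame["p"] < alpha
        frame = frame.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        frame["p_adj"] = pd.Series(dtype=float)
        frame["significant"] = pd.Series(dtype=bool)
    return EnrichmentResult(frame=frame, alpha=alpha)
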