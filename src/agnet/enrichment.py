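"""Gene-set overrepresentation analysis (hypergeometric + Bonferroni).

Given a query gene list (the members of an associative gene network) and
a collection of GO biological-process gene sets, each term is scored by
the upper tail of the hypergeometric distribution:

    p_raw = P[X >= k],  X ~ Hypergeometric(N, K, n)

where N is the background universe size, K the term size, n the query
size (after intersection with the universe) and k the observed overlap.
Raw p-values are Bonferroni-adjusted over the number of terms actually
tested and compared with the significance level ``alpha``.

An optional EASE-style variant (``ease=True``) scores ``P[X >= k-1]``
instead, for users comparing against DAVID output, which is known to use
that conservative modification; the plain hypergeometric tail is the
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "hypergeom_tail",
    "bonferroni",
    "enrich",
    "read_gmt",
    "results_to_frame",
    "write_results",
]


@dataclass(frozen=True)
class GeneSetCollection:
    """GO-BP terms (id -> name, members) over a background gene universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"gene set {tid!r} is empty")
            if not members <= self.universe:
                raise ValueError(f"gene set {tid!r} has members outside the universe")

    def __len__(self) -> int:
        return len(self.terms)

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def members(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]


def read_gmt(
    path: str | Path, universe: Iterable[str] | None = None
) -> GeneSetCollection:
    """Parse a GMT file (``term_id<TAB>term_name<TAB>gene1<TAB>gene2...``).

    The background universe defaults to the union of all annotated genes.
    A user-supplied *universe* overrides it; term members are then
    restricted to that universe and terms emptied by the restriction are
    dropped with a warning.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected term_id, term_name and "
                    "at least one gene"
                )
            tid, tname, genes = parts[0], parts[1], [p for p in parts[2:] if p]
            if tid in terms:
                raise ValueError(f"{path}: duplicate term id {tid!r}")
            terms[tid] = (tname, frozenset(genes))
    if universe is None:
        uni = frozenset().union(*(m for _, m in terms.values())) if terms else frozenset()
    else:
        uni = frozenset(universe)
        restricted = {}
        dropped = []
        for tid, (tname, members) in terms.items():
            kept = members & uni
            if kept:
                restricted[tid] = (tname, kept)
            else:
                dropped.append(tid)
        if dropped:
            warnings.warn(
                f"{len(dropped)} term(s) had no members in the supplied "
                f"universe and were dropped (e.g. {dropped[:3]})",
                stacklevel=2,
            )
        terms = restricted
    return GeneSetCollection(terms=terms, universe=uni)


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's overlap counts and raw/adjusted p-values.

    k: overlap; n: effective query size; K: term size; N: universe size;
    ``p_adj = min(1, m * p_raw)`` with m the number of tested terms.
    """

    term_id: str
    term_name: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adj: float
    significant: bool


def hypergeom_tail(k, n, K, N):
    """Upper-tail probability ``P[X >= k]`` for X ~ Hypergeometric(N, K, n).

    This is the probability that a sample of *n* genes drawn without
    replacement from a universe of *N* contains at least *k* of the *K*
    genes annotated to the term. Computed through the survival function,
    which is numerically stable far into the tail. Scalars or equal-length
    arrays are accepted; scalar input returns a float.
    """
    k_a, n_a, K_a, N_a = (np.asarray(x, dtype=np.int64) for x in (k, n, K, N))
    if np.any(k_a < 0) or np.any(n_a < 0) or np.any(K_a < 0) or np.any(N_a < 0):
        raise ValueError("hypergeom_tail: arguments must be nonnegative")
    if np.any(n_a > N_a) or np.any(K_a > N_a):
        raise ValueError("hypergeom_tail: requires n <= N and K <= N")
    if np.any(k_a > np.minimum(n_a, K_a)):
        raise ValueError("hypergeom_tail: requires k <= min(n, K)")
    out = stats.hypergeom.sf(k_a - 1, N_a, K_a, n_a)
    out = np.clip(out, 0.0, 1.0)
    if np.isscalar(k) or np.ndim(k) == 0:
        return float(out)
    return out


def bonferroni(p_raw: Sequence[float]) -> list[float]:
    """Bonferroni adjustment: multiply by the number of tests, cap at 1."""
    arr = np.asarray(p_raw, dtype=float)
    if arr.size and (np.any(arr < 0) or np.any(arr > 1) or np.any(np.isnan(arr))):
        raise ValueError("bonferroni: p-values must lie in [0, 1]")
    m = arr.size
    return list(np.minimum(1.0, m * arr))


def enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
    min_overlap: int = 1,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Overrepresentation of every gene set in *query*.

    Only terms with overlap ``k >= min_overlap`` are tested; the
    Bonferroni multiplier is the number of tested terms. Results are
    sorted by adjusted p-value, ties broken by term id, so output is
    byte-stable.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if min_overlap < 0:
        raise ValueError("min_overlap must be nonnegative")
    query = set(query)
    if not query:
        raise ValueError("enrich: empty query gene list")
    effective = query & sets.universe
    if not effective:
        raise ValueError(
            "enrich: no query gene is present in the background universe; "
            "check identifier spaces of query and gene sets"
        )
    n = len(effective)
    N = len(sets.universe)

    tested: list[tuple[str, str, int, int]] = []
    for tid in sorted(sets.terms):
        tname, members = sets.terms[tid]
        k = len(effective & members)
        if k >= min_overlap:
            tested.append((tid, tname, k, len(members)))
    if not tested:
        return []

    ks = np.array([t[2] for t in tested])
    Ks = np.array([t[3] for t in tested])
    score_k = np.maximum(ks - 1, 0) if ease else ks
    p_raw = hypergeom_tail(score_k, np.full_like(ks, n), Ks, np.full_like(ks, N))
    p_raw = np.atleast_1d(p_raw)
    p_adj = np.asarray(bonferroni(p_raw))

    results = [
        EnrichmentResult(
            term_id=tid,
            term_name=tname,
            k=int(k),
            n=n,
            K=int(K),
            N=N,
            p_raw=float(pr),
            p_adj=float(pa),
            significant=bool(pa < alpha),
        )
        for (tid, tname, k, K), pr, pa in zip(tested, p_raw, p_adj)
    ]
    results.sort(key=lambda r: (r.p_adj, r.term_id))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term_id", "term_name", "k", "n", "K", "N", "p_raw", "p_adj", "significant"]
    return pd.DataFrame(
        [{c: getattr(r, c) for c in cols} for r in results], columns=cols
    )


def write_results(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results as a TSV table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results_to_frame(results).to_csv(path, sep="\t", index=False)
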