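"""Over-representation analysis and permutation-NES transcription-factor ranking.

ORA tests each library term with the one-sided hypergeometric tail

    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n)

where N is the background (universe) size, n the universe-restricted query
size, K the term size, and k the overlap.  q-values are Benjamini-Hochberg
adjusted over all terms of the library, including zero-overlap terms (p = 1),
so the number of tests equals the library size.  The odds ratio comes from
the 2x2 overlap table, k(N-K-n+k) / ((K-k)(n-k)), reported as +inf when a
denominator cell is 0 and k > 0.

The background defaults to the union of all term genes; a fixed integer
override is accepted because web-tool backgrounds are generally not
recoverable.

Transcription-factor ranking uses an explicitly permutation-based NES: the
observed count of query genes inside a TF's target set is z-scored against
the counts of random same-size queries drawn uniformly from the universe.
This keeps the ranking semantics of motif-based NES tools (NES descending,
then target count) while being computable offline from a GMT regulon library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import EmptyQueryError, ValidationError
from .targets import GeneSet

__all__ = [
    "GeneSetLibrary",
    "EnrichmentRow",
    "TFRankRow",
    "ora",
    "bh_adjust",
    "top_terms",
    "tf_nes",
    "read_gmt",
    "write_gmt",
    "rows_to_frame",
]


@dataclass(frozen=True)
class GeneSetLibrary:
    """A named collection of gene-set terms with an enrichment universe.

    The universe defaults to the union of all term genes; every term must be
    a non-empty subset of the universe.
    """

    name: str
    terms: Mapping[str, frozenset[str]]
    universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self):
        terms = {t: frozenset(gs) for t, gs in self.terms.items()}
        if not terms:
            raise ValidationError(f"library {self.name!r} has no terms")
        for t, gs in terms.items():
            if not gs:
                raise ValidationError(f"term {t!r} is empty")
        universe = self.universe or frozenset().union(*terms.values())
        stray = {t for t, gs in terms.items() if not gs <= universe}
        if stray:
            raise ValidationError(
                f"terms with genes outside the universe: {sorted(stray)[:5]}"
            )
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "universe", frozenset(universe))

    def with_background(self, n: int) -> "GeneSetLibrary":
        """Pad the universe to a fixed background size with anonymous genes."""
        if n < len(self.universe):
            raise ValidationError(
                f"background {n} smaller than the library universe ({len(self.universe)})"
            )
        pad = {f"BG{i:07d}" for i in range(n - len(self.universe))}
        return GeneSetLibrary(self.name, self.terms, self.universe | pad)


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    overlap: GeneSet
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    odds_ratio: float
    rank: int


@dataclass(frozen=True)
class TFRankRow:
    tf: str
    n_targets_hit: int
    nes: float
    rank: int


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Step-up Benjamini-Hochberg adjustment, returned in input order."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return [float(x) for x in q]


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    a, b, c, d = k, K - k, n - k, N - K - n + k
    if b == 0 or c == 0:
        return float("inf") if k > 0 else 0.0
    return (a * d) / (b * c)


def ora(query: GeneSet, library: GeneSetLibrary) -> list[EnrichmentRow]:
    """One-sided hypergeometric over-representation of ``query`` in every term.

    Zero-overlap terms are retained with p = 1 so the BH family size equals
    the library size.  Rows are ranked by (q, p, term name).
    """
    q_genes = query.members & library.universe
    if not q_genes:
        raise EmptyQueryError(
            f"query {query.label!r} shares no genes with the {library.name!r} universe"
        )
    N = len(library.universe)
    n = len(q_genes)
    names = sorted(library.terms)
    ks, Ks, ps = [], [], []
    for t in names:
        term_genes = library.terms[t]
        k = len(term_genes & q_genes)
        K = len(term_genes)
        # survival function at k-1 is the upper tail P(X >= k); exact 1.0 at k=0
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
        ks.append(k)
        Ks.append(K)
        ps.append(min(max(p, 0.0), 1.0))
    qs = bh_adjust(ps)
    order = sorted(range(len(names)), key=lambda i: (qs[i], ps[i], names[i]))
    rows: list[EnrichmentRow] = []
    for rank, i in enumerate(order, 1):
        t = names[i]
        ov = frozenset(library.terms[t] & q_genes)
        rows.append(
            EnrichmentRow(
                term=t,
                overlap=GeneSet(f"overlap({t})", ov, {g: frozenset({t}) for g in ov}),
                k=ks[i],
                K=Ks[i],
                n=n,
                N=N,
                p=ps[i],
                q=qs[i],
                odds_ratio=_odds_ratio(ks[i], Ks[i], n, N),
                rank=rank,
            )
        )
    return rows


def top_terms(
    rows: Sequence[EnrichmentRow],
    by: Literal["q", "odds_ratio"] = "q",
    k: int = 5,
) -> list[EnrichmentRow]:
    """Best ``k`` rows under the stated key with deterministic tie-breaking
    (secondary p ascending, tertiary term name)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if by == "q":
        key = lambda r: (r.q, r.p, r.term)
    elif by == "odds_ratio":
        key = lambda r: (-r.odds_ratio, r.p, r.term)
    else:
        raise ValidationError(f"unknown ranking key {by!r}")
    return sorted(rows, key=key)[:k]


def tf_nes(
    query: GeneSet,
    tf_library: GeneSetLibrary,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[TFRankRow]:
    """Permutation-NES ranking of transcription-factor regulons.

    For each TF term, the observed number of query genes among its targets is
    z-scored against ``n_perm`` uniformly drawn same-size random queries from
    the universe (NES = 0 when the null standard deviation is 0).  Rows are
    ranked by NES descending, then hit count descending, then name.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    q_genes = sorted(query.members & tf_library.universe)
    n = len(q_genes)
    universe = sorted(tf_library.universe)
    if n == 0:
        raise EmptyQueryError("query shares no genes with the TF-library universe")
    if len(universe) < n:
        raise ValidationError("universe smaller than the query")
    uidx = {g: i for i, g in enumerate(universe)}
    names = sorted(tf_library.terms)
    term_mat = np.zeros((len(universe), len(names)), dtype=np.float64)
    for j, t in enumerate(names):
        for g in tf_library.terms[t]:
            term_mat[uidx[g], j] = 1.0
    obs_vec = np.zeros(len(universe))
    obs_vec[[uidx[g] for g in q_genes]] = 1.0
    observed = obs_vec @ term_mat

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(names)))
    sel = np.zeros(len(universe))
    for r in range(n_perm):
        pick = rng.choice(len(universe), size=n, replace=False)
        sel[:] = 0.0
        sel[pick] = 1.0
        null[r] = sel @ term_mat
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=0)
    nes = np.where(sd > 0, (observed - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    order = sorted(
        range(len(names)), key=lambda j: (-nes[j], -int(observed[j]), names[j])
    )
    return [
        TFRankRow(tf=names[j], n_targets_hit=int(observed[j]), nes=float(nes[j]), rank=r)
        for r, j in enumerate(order, 1)
    ]


# ---------------------------------------------------------------------------
# GMT I/O and tabular export

def read_gmt(path: str | Path, name: str | None = None,
             universe: frozenset[str] | None = None) -> GeneSetLibrary:
    """Read a GMT gene-set library (term, description, genes...)."""
    terms: dict[str, frozenset[str]] = {}
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{i}: GMT rows need term, description, >=1 gene")
        genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
        if not genes:
            raise ValidationError(f"{path}:{i}: term {parts[0]!r} has no genes")
        terms[parts[0]] = genes
    return GeneSetLibrary(name or Path(path).stem, terms, universe or frozenset())


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    lines = [
        "\t".join([t, library.name] + sorted(library.terms[t]))
        for t in sorted(library.terms)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """EnrichmentRow list -> DataFrame matching the TSV export layout."""
    return pd.DataFrame(
        {
            "term": [r.term for r in rows],
            "overlap_genes": [";".join(r.overlap.sorted()) for r in rows],
            "k": [r.k for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "N": [r.N for r in rows],
            "p": [r.p for r in rows],
            "q": [r.q for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "rank": [r.rank for r in rows],
        }
    )
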