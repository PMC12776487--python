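"""Gene-set over-representation analysis (ORA).

For a query of n genes drawn from a universe of N genes, of which K belong
to a given set, the overlap k is tested with the one-sided upper-tail
hypergeometric probability P(X >= k) — equivalently Fisher's exact test on
the 2x2 overlap table.  P-values are corrected with Benjamini–Hochberg;
only sets with k >= 1 are reported (zero-overlap rows carry no evidence of
over-representation and inflate the correction burden).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import UniverseError
from .types import GeneSetCollection


@dataclass
class EnrichmentRow:
    set_id: str
    set_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    p_adjusted: float
    significant: bool
    overlap: list[str]


def ora_test(query: set[str], target: set[str], universe: set[str]) -> float:
    """Upper-tail hypergeometric probability of the observed overlap."""
    if not universe:
        raise UniverseError("empty universe")
    if not set(query) <= set(universe):
        stray = sorted(set(query) - set(universe))[:5]
        raise UniverseError(f"query genes outside the universe: {stray} ...")
    if not set(target) <= set(universe):
        stray = sorted(set(target) - set(universe))[:5]
        raise UniverseError(f"target genes outside the universe: {stray} ...")
    N, K, n = len(set(universe)), len(set(target)), len(set(query))
    k = len(set(query) & set(target))
    # P(X >= k) = sf(k - 1)
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust(p_values: Sequence[float], method: str = "BH") -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values."""
    if method != "BH":
        raise ValueError(f"unsupported correction method {method!r}")
    if len(p_values) == 0:
        return []
    _, adjusted, _, _ = multipletests(list(p_values), method="fdr_bh")
    return [float(p) for p in adjusted]


def run_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    universe: Optional[set[str]] = None,
) -> list[EnrichmentRow]:
    """Test the query against every set with non-empty overlap.

    The universe defaults to the collection's own; a custom background may
    be supplied.  Rows are sorted by (adjusted p, raw p, set id) and flagged
    significant when adjusted p < alpha.
    """
    query = set(query)
    uni = set(universe) if universe is not None else set(collection.universe)
    if not query <= uni:
        stray = sorted(query - uni)[:5]
        raise UniverseError(f"query genes outside the universe: {stray} ...")

    tested = []
    for set_id in sorted(collection.sets):
        gs = collection.sets[set_id]
        target = set(gs.genes) & uni
        overlap = sorted(query & target)
        if not overlap:
            continue
        p = ora_test(query, target, uni)
        tested.append((gs, target, overlap, p))

    adjusted = adjust([t[3] for t in tested])
    rows = [
        EnrichmentRow(
            set_id=gs.set_id,
            set_name=gs.name,
            k=len(overlap),
            K=len(target),
            n=len(query),
            N=len(uni),
            p_value=p,
            p_adjusted=p_adj,
            significant=p_adj < alpha,
            overlap=overlap,
        )
        for (gs, target, overlap, p), p_adj in zip(tested, adjusted)
    ]
    rows.sort(key=lambda r: (r.p_adjusted, r.p_value, r.set_id))
    return rows


def enrichment_to_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "set_name": r.set_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "overlap": ",".join(r.overlap),
            }
            for r in rows
        ],
        columns=[
            "set_id", "set_name", "k", "K", "n", "N",
            "p_value", "p_adjusted", "significant", "overlap",
        ],
    )
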