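"""Hypergeometric over-representation analysis of a gene signature.

For a gene set with K members inside a reference universe of N genes, and
a signature of n mapped genes overlapping the set in k genes, the
enrichment p-value is the upper tail P(X >= k) of the hypergeometric
distribution — the chance a random n-gene draw from the universe overlaps
at least as much. The enrichment ratio (k/n)/(K/N) compares the fraction
of signature genes in the pathway with the pathway's fraction of the
universe; ratio > 1 marks the over-represented direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import hypergeom

from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "EnrichmentResult", "read_gmt", "enrich", "enrichment_to_frame"]

DEFAULT_MIN_GENES = 3
DEFAULT_ALPHA = 0.05


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")
        uni = set(self.universe)
        self.sets = {
            name: sorted(set(members) & uni) for name, members in self.sets.items()
        }


@dataclass
class EnrichmentResult:
    set_name: str
    k_overlap: int
    n_signature: int
    K_set: int
    N_universe: int
    enrichment_ratio: float
    p_value: float
    p_adj_bh: float | None = None
    enriched: bool = False


def read_gmt(path, universe: Sequence[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file (set name, description, members; tab-separated).

    Gene symbols are case-normalized to upper case; duplicate members are
    collapsed with a warning. When no universe is given, the union of all
    set members is used (log-noted: for a targeted panel pass the panel's
    gene list, for genome-wide analyses a genome-scale universe file —
    the choice changes every p-value).
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description, and at least one member"
                )
            name = fields[0]
            members = [g.strip().upper() for g in fields[2:] if g.strip()]
            if len(members) != len(set(members)):
                logger.warning(
                    "set %r (line %d) has duplicated members; deduplicating",
                    name, lineno,
                )
            sets[name] = sorted(set(members))
    if universe is None:
        universe = sorted({g for members in sets.values() for g in members})
        logger.info(
            "no universe supplied; defaulting to the union of set members "
            "(%d genes)", len(universe),
        )
    else:
        universe = sorted({g.strip().upper() for g in universe})
    return GeneSetCollection(sets=sets, universe=universe)


def enrich(
    signature_genes: Sequence[str],
    collection: GeneSetCollection,
    min_genes: int = DEFAULT_MIN_GENES,
    alpha: float = DEFAULT_ALPHA,
    min_genes_on: str = "overlap",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of the signature against each set.

    Signature genes are first mapped onto the universe (unmapped genes are
    logged and ignored). Sets whose overlap (or size, with
    ``min_genes_on='set'``) is below ``min_genes`` are excluded. Results
    are sorted by ascending p; p <= alpha flags ``enriched`` and a BH
    column is provided alongside.
    """
    if not signature_genes:
        raise ValueError("signature is empty")
    if min_genes_on not in ("overlap", "set"):
        raise ValueError("min_genes_on must be 'overlap' or 'set'")
    uni = set(collection.universe)
    sig = {g.strip().upper() for g in signature_genes}
    unmapped = sorted(sig - uni)
    if unmapped:
        logger.warning("%d signature genes not in universe: %s", len(unmapped), unmapped)
    mapped = sig & uni
    n = len(mapped)
    N = len(uni)

    results: list[EnrichmentResult] = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(mapped & set(members))
        counted = k if min_genes_on == "overlap" else K
        if counted < min_genes:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        ratio = (k / n) / (K / N) if K > 0 and n > 0 else float("nan")
        results.append(
            EnrichmentResult(
                set_name=name,
                k_overlap=k,
                n_signature=n,
                K_set=K,
                N_universe=N,
                enrichment_ratio=ratio,
                p_value=p,
            )
        )
    padj = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, padj):
        r.p_adj_bh = float(q)
        r.enriched = r.p_value <= alpha
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "k": [r.k_overlap for r in results],
            "n": [r.n_signature for r in results],
            "K": [r.K_set for r in results],
            "N": [r.N_universe for r in results],
            "ratio": [r.enrichment_ratio for r in results],
            "p": [r.p_value for r in results],
            "p_BH": [r.p_adj_bh for r in results],
            "enriched": [r.enriched for r in results],
        }
    )
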