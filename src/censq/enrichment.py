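"""Over-representation analysis of miRNA target genes.

A miRNA→gene map (two-column TSV of validated interactions) turns the
significant miRNAs of a comparison into a query gene set; each pathway
of a GMT collection is then tested for overlap with the query by the
hypergeometric upper tail,

    p = P(X ≥ k),  X ~ Hypergeom(N, K, n),

with N the universe size, K the pathway size inside the universe, n
the query size and k the overlap.  By default the universe is every
gene reachable through the target map — the space the assay can speak
about — not the union of pathway genes.  FDR is Benjamini–Hochberg
across the pathways actually tested.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def read_target_map(path) -> dict[str, set[str]]:
    """Read a two-column (miRNA, gene) TSV into {miRNA: {genes}}.

    Gene symbols are uppercased; empty gene sets are not stored.
    """
    table = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if table.shape[1] < 2:
        raise ValueError("target map needs two columns: miRNA, gene")
    mirna_col, gene_col = table.columns[:2]
    out: dict[str, set[str]] = {}
    for mirna, genes in table.groupby(mirna_col)[gene_col]:
        symbols = {g.strip().upper() for g in genes.dropna() if g.strip()}
        if symbols:
            out[mirna] = symbols
    return out


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """Read a GMT file into {pathway_id: (description, {genes})}."""
    pathways: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, genes = parts[0], parts[1], parts[2:]
            pathways[name] = (desc, {g.strip().upper() for g in genes if g.strip()})
    return pathways


def map_targets(de_mirnas, target_map: dict[str, set[str]]) -> set[str]:
    """Union of validated target genes over the given miRNAs.

    miRNAs absent from the map contribute nothing and are logged.
    """
    genes: set[str] = set()
    unmapped = []
    for mirna in de_mirnas:
        if mirna in target_map:
            genes |= target_map[mirna]
        else:
            unmapped.append(mirna)
    if unmapped:
        logger.info("map_targets: no validated targets for %s", unmapped)
    return genes


def ora_test(
    query: set[str],
    pathways: dict[str, tuple[str, set[str]]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each pathway.

    Pathways are intersected with the universe first; empty ones are
    skipped.  Returns one row per tested pathway, sorted by FDR then p.
    """
    query = {g.upper() for g in query} & universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for pid, (desc, genes) in pathways.items():
        in_universe = genes & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(query & in_universe)
        # upper tail P(X >= k); k = 0 gives p = 1 exactly
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"pathway": pid, "description": desc, "k": k, "K": K, "n": n, "N": N,
             "p_value": min(p, 1.0)}
        )
    if not rows:
        return pd.DataFrame(
            columns=["pathway", "description", "k", "K", "n", "N", "p_value", "fdr"]
        )
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table.sort_values(["fdr", "p_value"]).reset_index(drop=True)


def enrich_de_mirnas(
    de_table: pd.DataFrame,
    target_map: dict[str, set[str]],
    pathways: dict[str, tuple[str, set[str]]],
    alpha: float = 0.05,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """ORA of the targets of significant miRNAs in one DE table."""
    sig = de_table.index[de_table["p_value"] < alpha]
    genes = map_targets(sig, target_map)
    if universe is None:
        universe = set().union(*target_map.values()) if target_map else set()
    if not genes:
        logger.warning("enrich_de_mirnas: empty query gene set, enrichment skipped")
        return pd.DataFrame(
            columns=["pathway", "description", "k", "K", "n", "N", "p_value", "fdr"]
        )
    return ora_test(genes, pathways, universe)
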