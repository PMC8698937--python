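"""Gene-set over-representation testing for DMR gene lists.

Upper-tail hypergeometric p per gene set, with optional
Benjamini–Hochberg adjustment across sets. Gene sets are read from GMT
files; symbols are uppercase-normalized throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise EnrichmentError(f"gene set {self.name!r} is empty")


def _norm(symbols: Iterable[str]) -> frozenset:
    return frozenset(s.strip().upper() for s in symbols if s and s.strip())


def make_gene_set(name: str, members: Iterable[str]) -> GeneSet:
    return GeneSet(name=name, members=_norm(members))


def read_gmt(path) -> List[GeneSet]:
    """Read GMT: one set per line, name <tab> description <tab> genes..."""
    sets = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EnrichmentError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets.append(make_gene_set(fields[0], fields[2:]))
    return sets


def hypergeometric_enrichment(
    hits: Iterable[str], gene_set: GeneSet, universe: Iterable[str]
) -> Dict[str, float]:
    """Upper-tail over-representation of ``hits`` in one gene set.

    p = P(X >= k) with population |universe|, successes |set ∩ universe|,
    draws |hits|. ``hits`` must be a subset of the universe.
    """
    uni: Set[str] = set(_norm(universe))
    if not uni:
        raise EnrichmentError("empty universe")
    hit_set = set(_norm(hits))
    if not hit_set <= uni:
        raise EnrichmentError(f"hits outside universe: {sorted(hit_set - uni)[:5]}")
    successes = gene_set.members & uni
    k = len(hit_set & successes)
    n_draw = len(hit_set)
    expected = n_draw * len(successes) / len(uni)
    p = float(hypergeom.sf(k - 1, len(uni), len(successes), n_draw))
    return {"overlap": k, "expected": expected, "p": min(p, 1.0),
            "set_size": len(successes), "n_hits": n_draw}


def enrich_table(
    hits: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
    adjust: bool = True,
) -> pd.DataFrame:
    """Enrichment over several gene sets, BH-adjusted across sets."""
    uni = list(universe)
    rows = []
    for gs in gene_sets:
        res = hypergeometric_enrichment(hits, gs, uni)
        res["gene_set"] = gs.name
        rows.append(res)
    df = pd.DataFrame(rows).set_index("gene_set")
    if adjust and len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values("p")


# Demonstration fixture: the aggressive-disease region gene panel plus the
# transcription-factor families over-represented in it.
REGION_GENE_PANEL = (
    "ALX1", "ANKHD1-EIF4EBP3", "ARHGAP15", "ATXN7", "AVPR1A", "BACH2",
    "C6orf174", "CD24", "CD247", "CLDN11", "CLVS2", "CSDAP1", "DLX6AS",
    "DNASE1L2", "ERBB4", "ESRP2", "FAM171A2", "FAM179A", "FBN2", "FBXO39",
    "FOXG1", "GABRB2", "GALNT13", "GJB6", "GLIPR1L2", "GNAS", "GNMT",
    "GRIK2", "HERC2", "HOXC11", "HOXD1", "HOXD11", "HOXD8", "HPSE2",
    "KHDRBS2", "KSR2", "LHX8", "LRP5", "MAPK8IP3", "MIR2277", "MSX2",
    "NKAIN3", "NKX6-2", "PAX7", "PCDH10", "PEG10", "PF4", "PHYHIPL",
    "PITX2", "POU4F2", "PPP2R5E", "PRH1", "PTPN13", "RBM33", "RPLP1",
    "RSPO2", "SFRP2", "SGCE", "SHROOM1", "SLC6A11", "SOX11", "SPATA18",
    "SPTBN1", "TRIM2", "TWIST1", "UPB1", "WDR60", "WDR8", "WNT6", "WT1",
    "WWP2", "ZBTB16", "ZNF471", "ZNF577", "ZNF714", "ZNF83", "ZSCAN1",
)

HOMEOBOX_GENES = (
    "ALX1", "HOXC11", "HOXD1", "HOXD8", "HOXD11", "LHX8", "MSX2",
    "NKX6-2", "PAX7", "POU4F2",
)
ZINC_FINGER_GENES = ("ZBTB16", "ZNF83", "ZNF471", "ZNF577", "ZNF714", "ZSCAN1")


def example_gene_sets() -> List[GeneSet]:
    """Built-in demo sets: homeobox and zinc-finger transcription factors."""
    return [
        make_gene_set("homeobox_tf", HOMEOBOX_GENES),
        make_gene_set("zinc_finger_tf", ZINC_FINGER_GENES),
        make_gene_set("homeobox_or_zinc_finger", HOMEOBOX_GENES + ZINC_FINGER_GENES),
    ]
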