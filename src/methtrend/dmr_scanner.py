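"""Differentially methylated region calling.

A DMR is a maximal run of at least ``min_cpgs`` manifest-consecutive CpGs
that all pass the per-site significance filter with the same trend
direction, with every adjacent genomic gap <= ``max_gap`` bp (inclusive).
Sites failing the filter break runs; they are never skipped over.

Two implementations are provided: a linear scan (production) and a
window-enumeration oracle (testing), which must agree exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .manifest_io import Manifest

_ORACLE_MAX_SITES = 10_000


@dataclass(frozen=True)
class ScannerConfig:
    min_cpgs: int = 7
    max_gap: int = 500
    site_p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.min_cpgs < 2:
            raise ValueError(f"min_cpgs must be >= 2, got {self.min_cpgs}")
        if self.max_gap < 1:
            raise ValueError(f"max_gap must be >= 1, got {self.max_gap}")
        if not 0.0 < self.site_p_threshold <= 1.0:
            raise ValueError(
                f"site_p_threshold must be in (0, 1], got {self.site_p_threshold}"
            )


@dataclass(frozen=True)
class DMR:
    chrom: str
    start: int  # position of first member CpG (1-based)
    end: int  # position of last member CpG (1-based)
    cpg_ids: tuple
    direction: int
    n_cpgs: int
    genes: frozenset = frozenset()
    island_context: Optional[str] = None
    region_context: Optional[str] = None
    min_p: float = float("nan")
    mean_slope: float = float("nan")

    def key(self) -> tuple:
        """Identity used when comparing scanner and oracle output."""
        return (self.chrom, self.cpg_ids, self.direction)


def classify_sites(
    trend_results: pd.DataFrame,
    config: ScannerConfig,
    manifest: Manifest,
) -> np.ndarray:
    """Per-CpG label in manifest order: ±1 if p < threshold, else 0.

    The threshold is a strict inequality (p exactly at the threshold is
    not significant).
    """
    missing = [cid for cid in manifest.cpg_ids if cid not in trend_results.index]
    if missing:
        raise ValueError(f"missing trend result for CpG(s): {missing[:5]}...")
    sub = trend_results.loc[manifest.cpg_ids]
    p = sub["p_trend"].to_numpy(float)
    direction = sub["direction"].to_numpy(int)
    return np.where(p < config.site_p_threshold, direction, 0)


def _stats_for(
    cpg_ids: Sequence[str], trend_results: Optional[pd.DataFrame]
) -> tuple:
    if trend_results is None:
        return float("nan"), float("nan")
    sub = trend_results.loc[list(cpg_ids)]
    return float(sub["p_trend"].min()), float(sub["slope"].mean())


def _make_dmr(
    manifest: Manifest,
    start_idx: int,
    end_idx: int,
    direction: int,
    trend_results: Optional[pd.DataFrame],
) -> DMR:
    members = manifest.sites[start_idx : end_idx + 1]
    ids = tuple(s.cpg_id for s in members)
    min_p, mean_slope = _stats_for(ids, trend_results)
    return DMR(
        chrom=members[0].chrom,
        start=members[0].pos,
        end=members[-1].pos,
        cpg_ids=ids,
        direction=int(direction),
        n_cpgs=len(ids),
        min_p=min_p,
        mean_slope=mean_slope,
    )


def scan_dmrs(
    manifest: Manifest,
    labels: Sequence[int],
    config: ScannerConfig = ScannerConfig(),
    trend_results: Optional[pd.DataFrame] = None,
) -> List[DMR]:
    """Single-pass maximal-run scan over the manifest.

    A run longer than ``min_cpgs`` is reported once; runs are returned in
    manifest (chromosome, coordinate) order.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(manifest):
        raise ValueError("labels must align with the manifest")
    sites = manifest.sites
    out: List[DMR] = []
    run_start = 0
    for i in range(1, len(sites) + 1):
        broken = (
            i == len(sites)
            or labels[i] == 0
            or labels[i] != labels[run_start]
            or sites[i].chrom != sites[i - 1].chrom
            or sites[i].pos - sites[i - 1].pos > config.max_gap
        )
        if broken:
            if labels[run_start] != 0 and i - run_start >= config.min_cpgs:
                out.append(
                    _make_dmr(manifest, run_start, i - 1, labels[run_start], trend_results)
                )
            run_start = i
    return out


def enumerate_dmrs_oracle(
    manifest: Manifest,
    labels: Sequence[int],
    config: ScannerConfig = ScannerConfig(),
    trend_results: Optional[pd.DataFrame] = None,
) -> List[DMR]:
    """Brute-force reference: enumerate every contiguous window, filter by
    the three DMR conditions, and keep only windows not contained in a
    larger qualifying window. Intended for small instances only."""
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if len(labels) != len(manifest):
        raise ValueError("labels must align with the manifest")
    if n > _ORACLE_MAX_SITES:
        raise ValueError(f"oracle limited to {_ORACLE_MAX_SITES} sites, got {n}")
    sites = manifest.sites
    # break indicator between adjacent sites k and k+1
    brk = np.ones(max(n - 1, 0), dtype=bool)
    for k in range(n - 1):
        brk[k] = (
            labels[k] == 0
            or labels[k + 1] == 0
            or labels[k] != labels[k + 1]
            or sites[k + 1].chrom != sites[k].chrom
            or sites[k + 1].pos - sites[k].pos > config.max_gap
        )
    cum = np.concatenate([[0], np.cumsum(brk)])

    def valid(i: int, j: int) -> bool:
        return (
            labels[i] != 0
            and j - i + 1 >= config.min_cpgs
            and cum[j] - cum[i] == 0
        )

    windows = [
        (i, j) for i in range(n) for j in range(i, n) if valid(i, j)
    ]
    maximal = [
        (i, j)
        for (i, j) in windows
        if not (i > 0 and valid(i - 1, j)) and not (j < n - 1 and valid(i, j + 1))
    ]
    return [
        _make_dmr(manifest, i, j, labels[i], trend_results) for (i, j) in maximal
    ]


def annotate_dmrs(dmrs: List[DMR], manifest: Manifest) -> List[DMR]:
    """Attach gene symbols (union over members) and majority-vote island and
    gene-region context to each DMR."""
    by_id = {s.cpg_id: s for s in manifest.sites}
    out = []
    for dmr in dmrs:
        members = [by_id[cid] for cid in dmr.cpg_ids]
        genes = frozenset(s.gene_symbol for s in members if s.gene_symbol)
        island = _majority([s.island_relation for s in members])
        region = _majority([s.gene_region for s in members])
        out.append(replace(dmr, genes=genes, island_context=island, region_context=region))
    return out


def _majority(values: List[str]) -> str:
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    # deterministic tie-break: highest count, then alphabetical
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def dmrs_to_frame(dmrs: List[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "n_cpgs": [d.n_cpgs for d in dmrs],
            "direction": [d.direction for d in dmrs],
            "genes": [";".join(sorted(d.genes)) for d in dmrs],
            "island_context": [d.island_context for d in dmrs],
            "region_context": [d.region_context for d in dmrs],
            "min_p": [d.min_p for d in dmrs],
            "mean_slope": [d.mean_slope for d in dmrs],
            "cpg_ids": [",".join(d.cpg_ids) for d in dmrs],
        }
    )


def write_bed(dmrs: List[DMR], path) -> None:
    """BED6 export: 0-based half-open, name = most recurrent member gene,
    score = −10·log10(min_p) capped at 1000, strand '.'."""
    with open(path, "w", encoding="utf-8") as fh:
        for d in dmrs:
            name = sorted(d.genes)[0] if d.genes else "NA"
            if d.min_p and not math.isnan(d.min_p) and d.min_p > 0:
                score = min(1000, int(round(-10.0 * math.log10(d.min_p))))
            else:
                score = 0
            fh.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\t{name}\t{score}\t.\n")


def score_against_truth(
    dmrs: List[DMR],
    truth_blocks,
    min_overlap_fraction: float = 0.5,
) -> dict:
    """Recovery metrics against spiked truth blocks.

    A block counts as recovered when some called DMR of the matching sign
    covers at least ``min_overlap_fraction`` of its members; a called DMR
    overlapping no block is a false call.
    """
    called_sets = [(set(d.cpg_ids), d.direction) for d in dmrs]
    truth_any: Set[str] = set()
    recovered = 0
    for block in truth_blocks:
        members = set(block.cpg_ids)
        truth_any |= members
        need = min_overlap_fraction * len(members)
        if any(
            sign == block.sign and len(ids & members) >= need
            for ids, sign in called_sets
        ):
            recovered += 1
    false_calls = sum(1 for ids, _ in called_sets if not ids & truth_any)
    n_true = len(list(truth_blocks))
    return {
        "n_true_blocks": n_true,
        "n_recovered": recovered,
        "sensitivity": recovered / n_true if n_true else float("nan"),
        "n_called": len(dmrs),
        "n_false": false_calls,
    }
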