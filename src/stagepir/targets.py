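"""piRNA-associated transcript identification and selection.

A candidate read associates with a transcript when its interval overlaps
the transcript's genomic span by >= 1 bp (introns included: intragenic-TE
piRNAs are frequently intronic).  Association is quantified in piRPM per
orientation, with audits for uniquely mapped reads (n_hits == 1) and for
reads overlapping TEs embedded in the transcript.  Top targets are ranked
by total piRPM with a floor of 70 piRPM, reproducible targets are breed
intersections, stage-level candidates are unions, and differential
association applies a 2-fold rule on pseudocounted piRPM.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .candidacy import CandidateSet
from .features import GeneModel, TEFeature

ASSOCIATION_COLUMNS = [
    "biotype",
    "sense_piRPM",
    "antisense_piRPM",
    "total_piRPM",
    "unique_fraction",
    "te_fraction",
]


def transcript_association(
    cands: CandidateSet,
    gene_models: Sequence[GeneModel],
    te_features: Sequence[TEFeature] = (),
) -> pd.DataFrame:
    """Per-transcript piRNA association table for one sample.

    Returns a DataFrame indexed by transcript_id with sense/antisense/total
    piRPM, the unique-mapper fraction and the embedded-TE fraction of the
    associating copies.  Only transcripts with >= 1 associating read appear.
    """
    if cands.denom == 0:
        raise ValueError(f"sample {cands.sample_id} has no candidates")
    tx_tree: dict[str, IntervalTree] = {}
    for i, m in enumerate(gene_models):
        tx_tree.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end, i)
    te_tree: dict[str, IntervalTree] = {}
    for j, t in enumerate(te_features):
        te_tree.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, j)
    # TEs embedded in (i.e. intersecting) each transcript's span
    embedded: dict[int, frozenset[int]] = {}
    for i, m in enumerate(gene_models):
        tree = te_tree.get(m.chrom)
        embedded[i] = (
            frozenset(iv.data for iv in tree.overlap(m.start, m.end)) if tree else frozenset()
        )

    acc: dict[int, dict[str, float]] = {}
    for r in cands.reads:
        tree = tx_tree.get(r.chrom)
        if not tree:
            continue
        hits = tree.overlap(r.start, r.end)
        if not hits:
            continue
        te_hits = te_tree.get(r.chrom)
        read_tes = (
            frozenset(iv.data for iv in te_hits.overlap(r.start, r.end))
            if te_hits
            else frozenset()
        )
        for iv in hits:
            i = iv.data
            m = gene_models[i]
            rec = acc.setdefault(
                i, {"sense": 0.0, "antisense": 0.0, "unique": 0.0, "te": 0.0}
            )
            key = "sense" if r.strand == m.strand else "antisense"
            rec[key] += r.copies
            if r.n_hits == 1:
                rec["unique"] += r.copies
            if read_tes & embedded[i]:
                rec["te"] += r.copies

    scale = 1e6 / cands.denom
    rows = {}
    for i, rec in acc.items():
        m = gene_models[i]
        total = rec["sense"] + rec["antisense"]
        rows[m.transcript_id] = {
            "biotype": m.biotype,
            "sense_piRPM": rec["sense"] * scale,
            "antisense_piRPM": rec["antisense"] * scale,
            "total_piRPM": total * scale,
            "unique_fraction": rec["unique"] / total,
            "te_fraction": rec["te"] / total,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    if df.empty:
        df = pd.DataFrame(columns=ASSOCIATION_COLUMNS)
    return df[ASSOCIATION_COLUMNS].sort_index().rename_axis("transcript_id")


def select_top_targets(
    table: pd.DataFrame, n: int = 500, min_pirpm: float = 70.0, by: str = "total_piRPM"
) -> list[str]:
    """Top-``n`` transcripts by ``by`` piRPM, floored at ``min_pirpm``.

    Ties are broken by ascending transcript id for determinism.  ``by`` may
    be switched to ``sense_piRPM`` or ``antisense_piRPM``.
    """
    if table.empty:
        return []
    kept = table[table[by] >= min_pirpm]
    # stable two-key sort: ascending id first, then descending piRPM
    ranked = kept.sort_index(kind="stable").sort_values(by=by, ascending=False, kind="stable")
    return list(ranked.index[:n])


def reproducible_targets(list_a: Iterable[str], list_b: Iterable[str]) -> list[str]:
    """Transcripts present in both replicate/breed target lists (sorted)."""
    return sorted(set(list_a) & set(list_b))


def stage_union(per_stage: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Union of per-stage target lists with per-stage membership flags."""
    sets = {stage: set(ids) for stage, ids in per_stage.items()}
    all_ids = sorted(set().union(*sets.values())) if sets else []
    return pd.DataFrame(
        {stage: [t in s for t in all_ids] for stage, s in sets.items()},
        index=pd.Index(all_ids, name="transcript_id"),
        dtype=bool,
    )


def differential_association(
    table_1: pd.DataFrame,
    table_2: pd.DataFrame,
    fold: float = 2.0,
    pseudo: float = 0.5,
    value: str = "total_piRPM",
) -> pd.DataFrame:
    """Transcripts with > ``fold`` change in pseudocounted piRPM.

    The 0.5-piRPM pseudocount makes the ratio defined for transcripts seen
    in only one stage; direction records which table is higher.  Symmetric
    in table order up to the direction flag.
    """
    v1 = table_1[value] if not table_1.empty else pd.Series(dtype=float)
    v2 = table_2[value] if not table_2.empty else pd.Series(dtype=float)
    joined = pd.concat([v1.rename("v1"), v2.rename("v2")], axis=1).fillna(0.0)
    a = joined["v1"] + pseudo
    b = joined["v2"] + pseudo
    ratio = pd.concat([a / b, b / a], axis=1).max(axis=1)
    out = pd.DataFrame(
        {
            "piRPM_1": joined["v1"],
            "piRPM_2": joined["v2"],
            "fold_change": ratio,
            "direction": ["up_in_2" if y > x else "up_in_1" for x, y in zip(a, b)],
        },
        index=joined.index,
    )
    out = out[out["fold_change"] > fold].sort_index()
    return out.rename_axis("transcript_id")


def biotype_breakdown(
    targets: Iterable[str], gene_models: Sequence[GeneModel]
) -> dict[str, int]:
    """Counts per biotype; targets missing from the models go under
    ``unannotated`` rather than being dropped silently."""
    biotype = {m.transcript_id: m.biotype for m in gene_models}
    counts: dict[str, int] = {}
    for t in targets:
        key = biotype.get(t, "unannotated")
        counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items()))
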