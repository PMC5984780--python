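"""piRNA cluster detection, merging and stage-resolved quantification.

Detection is a deterministic density detector in the spirit of proTRAC:
position-sorted candidates are chained into runs wherever consecutive 5'
ends are within ``max_gap``, and a run is reported as a cluster when it
clears the distinct-sequence, copy, density, 1U-fraction and length gates.
Clusters are classified as mono-directional, bi-directional (two contiguous
opposite-strand blocks, i.e. divergent arms) or dual-strand (interleaved
strands).  Per-sample clusters are merged across samples by genomic
overlap, boundaries are extended over expressed transcripts (FPKM >= 1 in
at least one RNA-seq dataset) to a fixpoint, and expression is quantified
as piRPKM (piRNA reads per kilobase of cluster per million candidate
reads).  Stage-enriched clusters (piRCs) are those whose top stage is both
above an expression cutoff and >= 1.5-fold over the second-highest stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .candidacy import CandidateSet, MappedRead
from .features import GeneModel
from .signatures import five_prime

MODES = ("mono_plus", "mono_minus", "bidirectional", "dual_strand")


@dataclass
class ClusterParams:
    """Detection gates (all config-exposed; defaults as documented)."""

    max_gap: int = 5000  # nt between consecutive 5' ends within a run
    min_distinct: int = 5  # distinct sequences
    min_copies: int = 10  # copy-weighted reads
    min_density: float = 10.0  # copies per kb of cluster span
    min_u1: float = 0.5  # copy-weighted 1U fraction
    min_len: int = 1000  # nt span
    mono_threshold: float = 0.9  # copies on one strand => mono
    split_violation: float = 0.10  # tolerated off-block copies => bidirectional


@dataclass
class PiCluster:
    """One detected cluster in one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    mode: str
    n_reads: int  # copy-weighted
    n_distinct: int
    u1_fraction: float
    density: float  # copies per kb
    reads: list[MappedRead] = field(default_factory=list, repr=False)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MergedCluster:
    """A cross-sample merged (and possibly transcript-extended) cluster."""

    cluster_id: str
    chrom: str
    start: int
    end: int
    members: list[PiCluster] = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# detection


def classify_mode(
    reads: Sequence[MappedRead],
    mono_threshold: float = 0.9,
    split_violation: float = 0.10,
) -> str:
    """Directionality mode of a cluster's reads (copy-weighted).

    mono if >= ``mono_threshold`` of copies lie on one strand; otherwise
    bidirectional if some split point along the 5'-sorted reads leaves at
    most ``split_violation`` of copies outside two contiguous opposite-
    strand blocks; otherwise dual_strand.
    """
    if not reads:
        raise ValueError("cannot classify an empty cluster")
    order = sorted(reads, key=lambda r: (five_prime(r), r.strand, r.sequence))
    copies = np.array([r.copies for r in order], dtype=float)
    is_plus = np.array([r.strand == "+" for r in order])
    total = copies.sum()
    plus_total = copies[is_plus].sum()
    if plus_total / total >= mono_threshold:
        return "mono_plus"
    if (total - plus_total) / total >= mono_threshold:
        return "mono_minus"
    cum_plus = np.concatenate([[0.0], np.cumsum(copies * is_plus)])
    cum_minus = np.concatenate([[0.0], np.cumsum(copies * ~is_plus)])
    # orientation minus-block then plus-block: violations = plus copies in
    # the prefix + minus copies in the suffix (and vice versa)
    viol_mp = cum_plus[:-1] + (cum_minus[-1] - cum_minus[:-1])
    viol_pm = cum_minus[:-1] + (cum_plus[-1] - cum_plus[:-1])
    best = min(
        float(np.min(viol_mp)),
        float(np.min(viol_pm)),
        float(cum_plus[-1]),  # split after the last read
        float(cum_minus[-1]),
    )
    return "bidirectional" if best <= split_violation * total else "dual_strand"


def detect_clusters(cands: CandidateSet, params: ClusterParams | None = None) -> list[PiCluster]:
    """Deterministic density detection of piRNA clusters in one sample."""
    params = params or ClusterParams()
    by_chrom: dict[str, list[MappedRead]] = {}
    for r in cands.reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    out = []
    for chrom in sorted(by_chrom):
        reads = sorted(by_chrom[chrom], key=lambda r: (five_prime(r), r.strand, r.sequence))
        fp = np.array([five_prime(r) for r in reads])
        breaks = np.nonzero(np.diff(fp) > params.max_gap)[0] + 1
        for run in np.split(np.arange(len(reads)), breaks):
            members = [reads[i] for i in run]
            copies = sum(r.copies for r in members)
            distinct = len({r.sequence for r in members})
            start = min(r.start for r in members)
            end = max(r.end for r in members)
            span = end - start
            density = copies / (span / 1000.0)
            u1 = sum(r.copies for r in members if r.sequence[0] == "T") / copies
            if (
                span >= params.min_len
                and distinct >= params.min_distinct
                and copies >= params.min_copies
                and density >= params.min_density
                and u1 >= params.min_u1
            ):
                out.append(
                    PiCluster(
                        sample_id=cands.sample_id,
                        chrom=chrom,
                        start=start,
                        end=end,
                        mode=classify_mode(
                            members, params.mono_threshold, params.split_violation
                        ),
                        n_reads=copies,
                        n_distinct=distinct,
                        u1_fraction=u1,
                        density=density,
                        reads=members,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# merging and extension


def merge_clusters(cluster_lists: Iterable[Sequence[PiCluster]]) -> list[MergedCluster]:
    """Union same-chromosome clusters overlapping by >= 1 bp, transitively.

    Strand-agnostic (dual-strand clusters make stranded merging ill-defined).
    Output intervals are pairwise disjoint per chromosome, sorted, with
    deterministic ids.
    """
    flat: list[PiCluster] = [c for lst in cluster_lists for c in lst]
    by_chrom: dict[str, list[PiCluster]] = {}
    for c in flat:
        by_chrom.setdefault(c.chrom, []).append(c)
    merged: list[MergedCluster] = []
    for chrom in sorted(by_chrom):
        cs = sorted(
            by_chrom[chrom],
            key=lambda c: (c.start, c.end, getattr(c, "sample_id", "")),
        )
        cur_start, cur_end, cur_members = None, None, []
        for c in cs:
            if cur_start is None or c.start >= cur_end:  # no 1-bp overlap
                if cur_start is not None:
                    merged.append(MergedCluster("", chrom, cur_start, cur_end, cur_members))
                cur_start, cur_end, cur_members = c.start, c.end, [c]
            else:
                cur_end = max(cur_end, c.end)
                cur_members.append(c)
        if cur_start is not None:
            merged.append(MergedCluster("", chrom, cur_start, cur_end, cur_members))
    merged.sort(key=lambda m: (m.chrom, m.start))
    for i, m in enumerate(merged, start=1):
        m.cluster_id = f"piRC_{i:05d}"
    return merged


def _expressed_transcripts(
    gene_models: Sequence[GeneModel], fpkm_table: pd.DataFrame, min_fpkm: float
) -> list[GeneModel]:
    if fpkm_table.empty:
        return []
    expressed = set(fpkm_table.index[(fpkm_table >= min_fpkm).any(axis=1)])
    return [m for m in gene_models if m.transcript_id in expressed]


def extend_once(
    registry: Sequence[MergedCluster], transcripts: Sequence[GeneModel]
) -> bool:
    """One growth pass; returns True if any boundary moved (internal step)."""
    trees: dict[str, IntervalTree] = {}
    for m in transcripts:
        trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end)
    changed = False
    for c in registry:
        tree = trees.get(c.chrom)
        if not tree:
            continue
        hits = tree.overlap(c.start, c.end)
        if not hits:
            continue
        new_start = min(c.start, min(iv.begin for iv in hits))
        new_end = max(c.end, max(iv.end for iv in hits))
        if (new_start, new_end) != (c.start, c.end):
            c.start, c.end = new_start, new_end
            changed = True
    return changed


def extend_by_transcripts(
    registry: Sequence[MergedCluster],
    gene_models: Sequence[GeneModel],
    fpkm_table: pd.DataFrame,
    min_fpkm: float = 1.0,
    max_iter: int = 50,
) -> list[MergedCluster]:
    """Grow cluster boundaries over expressed transcripts, to a fixpoint.

    A cluster overlapping (>= 1 bp) a transcript with FPKM >= ``min_fpkm``
    in at least one dataset is widened to cover the transcript span; newly
    overlapped transcripts are re-checked until nothing moves.  Boundaries
    only ever grow (monotone operator), so the fixpoint exists; the
    iteration guard is a safety net against malformed inputs.
    """
    transcripts = _expressed_transcripts(gene_models, fpkm_table, min_fpkm)
    registry = list(registry)
    for _ in range(max_iter):
        if not extend_once(registry, transcripts):
            return registry
    raise RuntimeError(f"transcript extension did not converge in {max_iter} passes")


def clusterable_copies(registry: Sequence[MergedCluster], cands: CandidateSet) -> int:
    """Copy-weighted candidates whose 5' end falls inside any cluster."""
    trees: dict[str, IntervalTree] = {}
    for c in registry:
        trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end)
    total = 0
    for r in cands.reads:
        tree = trees.get(r.chrom)
        if tree and tree.overlap(five_prime(r), five_prime(r) + 1):
            total += r.copies
    return total


# ---------------------------------------------------------------------------
# quantification and stage enrichment

DEFAULT_STAGE_GROUPS = {
    "BC": ("BC",),
    "PGC": ("PGC",),
    "EG": ("E11G", "E14G"),
    "AT": ("AT",),
}


def quantify_pirpkm(
    registry: Sequence[MergedCluster],
    samples: Mapping[str, CandidateSet],
    stage_groups: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster x sample and cluster x stage piRPKM matrices.

    A read is assigned to a cluster iff its 5' position lies within the
    half-open cluster interval; piRPKM = copies / (cluster kb x candidate
    millions).  A stage's value is the arithmetic mean over its member
    samples (e.g. EG averages the E11 and E14 gonad samples).
    """
    ids = [c.cluster_id for c in registry]
    sample_ids = sorted(samples)
    mat = pd.DataFrame(0.0, index=ids, columns=sample_ids)
    trees: dict[str, IntervalTree] = {}
    for c in registry:
        trees.setdefault(c.chrom, IntervalTree()).addi(c.start, c.end, c.cluster_id)
    for sid in sample_ids:
        cs = samples[sid]
        if cs.denom == 0:
            raise ValueError(f"sample {sid} has no candidates (denom=0)")
        copies: dict[str, int] = {}
        for r in cs.reads:
            tree = trees.get(r.chrom)
            if not tree:
                continue
            fp = five_prime(r)
            for iv in tree.overlap(fp, fp + 1):
                copies[iv.data] = copies.get(iv.data, 0) + r.copies
        denom_millions = cs.denom / 1e6
        for c in registry:
            kb = (c.end - c.start) / 1000.0
            mat.loc[c.cluster_id, sid] = copies.get(c.cluster_id, 0) / kb / denom_millions
    groups = stage_groups or _groups_from_samples(samples)
    stage_mat = pd.DataFrame(index=ids)
    for stage, members in groups.items():
        present = [m for m in members if m in mat.columns]
        if present:
            stage_mat[stage] = mat[present].mean(axis=1)
    return mat, stage_mat


def _groups_from_samples(samples: Mapping[str, CandidateSet]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for sid in sorted(samples):
        stage = samples[sid].stage
        group = "EG" if stage in ("E11G", "E14G") else stage
        groups.setdefault(group, []).append(sid)
    return groups


def classify_stage_enrichment(
    stage_matrix: pd.DataFrame, min_expr: float = 0.1, fold: float = 1.5
) -> pd.Series:
    """Label each cluster by stage enrichment.

    ``<stage>-piRC`` when the top stage is >= ``min_expr`` piRPKM and
    >= ``fold`` x the second-highest stage; ``not_expressed`` when every
    stage is below ``min_expr``; ``shared`` otherwise (ties at the top can
    never satisfy the fold rule).
    """
    if stage_matrix.shape[1] < 2:
        raise ValueError("need >= 2 stages to classify enrichment")
    labels = {}
    stages = list(stage_matrix.columns)
    for cid, row in stage_matrix.iterrows():
        vals = row.to_numpy(dtype=float)
        order = np.argsort(-vals, kind="stable")
        top, second = vals[order[0]], vals[order[1]]
        if (vals < min_expr).all():
            labels[cid] = "not_expressed"
        elif top >= min_expr and top >= fold * second and top > second:
            labels[cid] = f"{stages[order[0]]}-piRC"
        else:
            labels[cid] = "shared"
    return pd.Series(labels, name="enrichment")


# ---------------------------------------------------------------------------
# MDS embedding


def mds_embedding(
    sample_matrix: pd.DataFrame, k: int = 2, pseudo: float = 0.01
) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical (Torgerson) MDS of samples by cluster expression.

    Distances are Euclidean on log10(piRPKM + ``pseudo``) profiles.  Returns
    sample coordinates and the fraction of (positive) eigenvalue mass per
    returned dimension — the variation each dimension explains.
    """
    if sample_matrix.shape[1] < 3:
        raise ValueError("need >= 3 samples for an MDS embedding")
    X = np.log10(sample_matrix.to_numpy(dtype=float).T + pseudo)
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.clip(d2, 0.0, None)
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = np.clip(evals, 0.0, None)
    coords = evecs[:, :k] * np.sqrt(pos[:k])
    total = pos.sum()
    fractions = pos[:k] / total if total > 0 else np.zeros(k)
    coord_df = pd.DataFrame(
        coords, index=sample_matrix.columns, columns=[f"dim{i + 1}" for i in range(k)]
    )
    return coord_df, fractions


# ---------------------------------------------------------------------------
# synteny


def synteny_check(
    anchors: Mapping[str, Mapping[str, tuple]],
    clusters_by_species: Mapping[str, Sequence[tuple[str, int, int]]],
) -> pd.Series:
    """Flag anchor pairs with a cluster between both species' anchor genes.

    ``anchors`` maps an anchor-pair name to, per species, a tuple
    ``(chrom, (geneA_start, geneA_end), (geneB_start, geneB_end))`` with
    geneA before geneB.  An anchor pair is conserved iff every species has
    >= 1 cluster wholly inside the open interval between its two anchor
    genes (a cluster straddling either gene does not count).
    """
    out = {}
    for name, per_species in anchors.items():
        conserved = True
        for species, (chrom, gene_a, gene_b) in per_species.items():
            a_start, a_end = gene_a
            b_start, b_end = gene_b
            if a_end > b_start:
                raise ValueError(
                    f"anchor {name!r}/{species}: genes overlap or are unordered"
                )
            found = any(
                c == chrom and a_end <= s and e <= b_start
                for c, s, e in clusters_by_species.get(species, [])
            )
            conserved = conserved and found
        out[name] = conserved
    return pd.Series(out, name="conserved", dtype=bool)


# ---------------------------------------------------------------------------
# table output


def clusters_to_bed(clusters: Sequence[PiCluster]) -> pd.DataFrame:
    rows = [
        (c.chrom, c.start, c.end, c.mode, c.n_reads, ".")
        for c in sorted(clusters, key=lambda c: (c.chrom, c.start))
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def registry_to_bed(registry: Sequence[MergedCluster]) -> pd.DataFrame:
    rows = [
        (c.chrom, c.start, c.end, c.cluster_id, len(c.members), ".") for c in registry
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
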