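"""Synthetic reference bundle and stage-dependent small-RNA read simulator.

The generator emulates the statistical structure the analysis assumes: a
random genome carrying planted transposable-element (TE) copies (per-family
consensus sequences mutated at a stated divergence), gene models with exon
blocks and biotypes, rRNA/tRNA/miRNA loci whose sequences double as the
contaminant blacklists, a transcript FPKM table, and stage-dependent piRNA
pools emitted from planted clusters of all three directionality modes.

Every emitted read is an exact substring of the genome (strand-adjusted),
so the no-mismatch mapping contract holds by construction.  Ping-pong pairs
exploit a complementarity identity: when the plus-strand mate's 5' genome
base is T and the base 9 nt downstream is A, both mates automatically carry
1U and 10A — no genome patching is needed.  A full ground-truth manifest
(per-read class, source locus, coordinates) accompanies each sample, which
makes filter-cascade recall/precision and association profiles exactly
computable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .candidacy import DEFAULT_ADAPTOR, CandidateSet, _blacklist_blob
from .dna import A, T, as_bytes, random_dna, revcomp
from .features import GeneModel, NcRNALocus, TEFeature
from . import io as spio

STAGES = ("BC", "PGC", "E11G", "E14G", "AT")

#: default sample sheet: one sample per developmental stage
DEFAULT_SAMPLES: dict[str, str] = {s: s for s in STAGES}

READ_CLASSES = ("piRNA_cluster", "piRNA_TE", "rRNA_frag", "tRNA_frag", "miRNA", "degradation")

MANIFEST_COLUMNS = [
    "read_id",
    "sample_id",
    "stage",
    "cls",
    "source",
    "chrom",
    "start",
    "end",
    "strand",
    "length",
    "sequence",
    "expected_candidate",
]


# ---------------------------------------------------------------------------
# parameter and truth containers


@dataclass(frozen=True)
class ClusterSpec:
    """A planted piRNA cluster and its stage-dependent emission profile."""

    chrom: str
    start: int
    end: int
    mode: str  # mono_plus | mono_minus | bidirectional | dual_strand
    stage_weights: Mapping[str, float]
    n_reads: int  # base read count; stage emission = round(n_reads * weight)
    u1_prob: float = 0.85
    pingpong_frac: float = 0.1
    length_mean: float = 27.0
    length_sd: float = 2.0
    name: str = ""

    def __post_init__(self):
        if self.end - self.start < 1000:
            raise ValueError("cluster span must be >= 1000 nt")
        if not 0 <= self.u1_prob <= 1 or not 0 <= self.pingpong_frac <= 1:
            raise ValueError("u1_prob and pingpong_frac must lie in [0, 1]")
        if self.mode not in ("mono_plus", "mono_minus", "bidirectional", "dual_strand"):
            raise ValueError(f"unknown cluster mode {self.mode!r}")
        if any(w < 0 for w in self.stage_weights.values()):
            raise ValueError("stage weights must be >= 0")

    @property
    def label(self) -> str:
        return self.name or f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class NoiseSpec:
    """Non-cluster read counts per sample (all copy counts, not fractions)."""

    degradation: int = 100
    te_reads: int = 8000
    te_antisense_prob: float = 0.75
    rrna_frags: int = 3000
    trna_frags: int = 1500
    known_mirna: int = 1500
    predicted_mirna: int = 800


@dataclass(frozen=True)
class ReferenceParams:
    """Sizing of the synthetic reference bundle."""

    genome_size: int = 1_000_000
    n_chroms: int = 2
    te_families: tuple[str, ...] = ("CR1-B", "CR1-C", "CR1-F", "CR1-H")
    te_copies_per_family: int = 12
    te_consensus_len: int = 1500
    te_divergence: float = 0.10
    te_block_count: int = 4  # runs of consecutive copies hosting TE clusters
    te_block_size: int = 3
    n_genes: int = 30
    n_rrna: int = 2
    n_trna: int = 5
    n_known_mirna: int = 5
    n_predicted_mirna: int = 3
    rrna_len: int = 1500
    trna_len: int = 75
    mirna_len: int = 80

    def __post_init__(self):
        if self.genome_size < 100_000:
            raise ValueError("genome size must be >= 100 kb")


@dataclass(eq=False)
class ReferenceBundle:
    """Synthetic genome plus annotations (0-based half-open coordinates)."""

    genome: dict[str, str]
    te_features: list[TEFeature]
    gene_models: list[GeneModel]
    ncrna_loci: list[NcRNALocus]
    fpkm_table: pd.DataFrame
    te_consensus: dict[str, str] = field(default_factory=dict)

    def blacklists(self) -> dict[str, dict[str, str]]:
        """Contaminant blacklists in cascade order (sense sequences)."""
        out = {"rrna_trna": {}, "known_mirna": {}, "predicted_mirna": {}}
        for locus in self.ncrna_loci:
            if locus.ncrna_class in ("rRNA", "tRNA"):
                out["rrna_trna"][locus.name] = locus.sequence
            elif locus.ncrna_class == "known_miRNA":
                out["known_mirna"][locus.name] = locus.sequence
            else:
                out["predicted_mirna"][locus.name] = locus.sequence
        return out


@dataclass
class TruthManifest:
    """Ground truth for one or more simulated samples."""

    reads: pd.DataFrame  # MANIFEST_COLUMNS
    cluster_specs: list[ClusterSpec] = field(default_factory=list)

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.reads[self.reads["sample_id"] == sample_id]

    def class_counts(self, sample_id: str) -> pd.Series:
        return self.for_sample(sample_id)["cls"].value_counts()

    @staticmethod
    def concat(manifests: Sequence["TruthManifest"]) -> "TruthManifest":
        reads = pd.concat([m.reads for m in manifests], ignore_index=True)
        specs = list(manifests[0].cluster_specs) if manifests else []
        return TruthManifest(reads=reads, cluster_specs=specs)


# ---------------------------------------------------------------------------
# reference construction


class _Cursor:
    """Sequential interval allocator on one chromosome (sizing-checked)."""

    def __init__(self, chrom: str, length: int, start_margin: int = 1000):
        self.chrom = chrom
        self.length = length
        self.pos = start_margin

    def take(self, size: int, gap: int) -> tuple[int, int]:
        self.pos += gap
        start, end = self.pos, self.pos + size
        if end > self.length - 1000:
            raise ValueError(
                f"requested features exceed capacity of {self.chrom} "
                f"({self.length} bp); reduce feature counts or grow the genome"
            )
        self.pos = end
        return start, end


def _mutate(consensus: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence <= 0:
        return consensus
    b = list(consensus)
    hits = np.nonzero(rng.random(len(b)) < divergence)[0]
    for i in hits:
        choices = [c for c in "ACGT" if c != b[i]]
        b[i] = choices[rng.integers(0, 3)]
    return "".join(b)


def build_reference(params: ReferenceParams | None = None, seed: int = 42) -> ReferenceBundle:
    """Deterministically build the synthetic reference bundle.

    TE copies are mutated copies of per-family consensus sequences written
    into the genome; ncRNA loci carry their own random sequences (recorded
    sense-strand, also written into the genome so contaminant fragments map
    exactly).  Gene models get exon blocks, strands and biotypes; every
    third gene hosts a TE copy inside an intron so intragenic-TE piRNA
    targeting is representable.  Raises a sizing error when the requested
    features do not fit the genome.
    """
    params = params or ReferenceParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))

    # chromosome sizes: first chromosome gets a double share
    shares = np.array([2.0] + [1.0] * (params.n_chroms - 1))
    sizes = (shares / shares.sum() * params.genome_size).astype(int)
    chrom_names = [f"chr{i + 1}" for i in range(params.n_chroms)]
    genome = {
        name: np.array(list("ACGT"))[rng.integers(0, 4, int(size))]
        for name, size in zip(chrom_names, sizes)
    }

    consensus = {
        fam: random_dna(rng, params.te_consensus_len) for fam in params.te_families
    }
    te_features: list[TEFeature] = []
    ncrna_loci: list[NcRNALocus] = []
    gene_models: list[GeneModel] = []

    def plant_te(chrom: str, start: int, fam: str, strand: str) -> None:
        copy = _mutate(consensus[fam], params.te_divergence, rng)
        seg = copy if strand == "+" else revcomp(copy)
        genome[chrom][start : start + len(seg)] = list(seg)
        te_features.append(TEFeature(chrom, start, start + len(seg), strand, fam))

    def plant_ncrna(chrom: str, cur: _Cursor, name: str, cls: str, length: int) -> None:
        start, end = cur.take(length, int(rng.integers(150, 400)))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = random_dna(rng, length)
        seg = seq if strand == "+" else revcomp(seq)
        genome[chrom][start:end] = list(seg)
        ncrna_loci.append(NcRNALocus(name, cls, chrom, start, end, strand, seq))

    fam_cycle = list(params.te_families)
    te_budget = {fam: params.te_copies_per_family for fam in fam_cycle}

    def next_family() -> str:
        for _ in range(len(fam_cycle)):
            fam = fam_cycle.pop(0)
            fam_cycle.append(fam)
            if te_budget[fam] > 0:
                te_budget[fam] -= 1
                return fam
        raise ValueError("TE copy budget exhausted; raise te_copies_per_family")

    # --- chromosome 1: ncRNA zone, TE blocks, genes, scattered TEs --------
    cur1 = _Cursor(chrom_names[0], int(sizes[0]))
    for i in range(params.n_rrna):
        plant_ncrna(chrom_names[0], cur1, f"rrna{i + 1}", "rRNA", params.rrna_len)
    for i in range(params.n_trna):
        plant_ncrna(chrom_names[0], cur1, f"trna{i + 1}", "tRNA", params.trna_len)
    for i in range(params.n_known_mirna):
        plant_ncrna(chrom_names[0], cur1, f"known_mir{i + 1}", "known_miRNA", params.mirna_len)
    for i in range(params.n_predicted_mirna):
        plant_ncrna(chrom_names[0], cur1, f"pred_mir{i + 1}", "predicted_miRNA", params.mirna_len)

    # TE blocks: consecutive copies separated from everything else by wide
    # gaps so each block is an isolated cluster host
    for _b in range(params.te_block_count):
        fam = max(te_budget, key=lambda f: (te_budget[f], f))
        if te_budget[fam] < params.te_block_size:
            raise ValueError(
                "TE copy budget too small for the requested TE blocks; "
                "raise te_copies_per_family or reduce te_block_count/size"
            )
        te_budget[fam] -= params.te_block_size
        for j in range(params.te_block_size):
            gap = int(rng.integers(12_000, 18_000)) if j == 0 else int(rng.integers(20, 60))
            start, _ = cur1.take(params.te_consensus_len, gap)
            strand = "+" if rng.random() < 0.5 else "-"
            plant_te(chrom_names[0], start, fam, strand)

    # genes (distributed ~proportionally to chromosome size)
    n_genes_c1 = int(round(params.n_genes * sizes[0] / sizes.sum()))
    biotype_cycle = [
        "protein_coding",
        "protein_coding",
        "uncharacterized",
        "protein_coding",
        "uncharacterized",
        "snoRNA",
    ]

    def plant_gene(chrom: str, cur: _Cursor, gi: int) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = biotype_cycle[gi % len(biotype_cycle)]
        host_te = gi % 3 == 1 and any(te_budget.values())
        if host_te:
            intron_len = params.te_consensus_len + 800
            exon_lens = [500, 500]
            intron_lens = [intron_len]
        else:
            n_exons = int(rng.integers(2, 5))
            exon_lens = [int(rng.integers(300, 800)) for _ in range(n_exons)]
            intron_lens = [int(rng.integers(400, 1200)) for _ in range(n_exons - 1)]
        span = sum(exon_lens) + sum(intron_lens)
        start, end = cur.take(span, int(rng.integers(8_000, 12_000)))
        exons = []
        pos = start
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if k < len(intron_lens):
                pos += intron_lens[k]
        gene_models.append(
            GeneModel(
                transcript_id=f"tx{gi + 1:03d}",
                gene_id=f"gene{gi + 1:03d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                biotype=biotype,
                exons=tuple(exons),
            )
        )
        if host_te:
            te_start = exons[0][1] + 400
            plant_te(chrom, te_start, next_family(), "+" if rng.random() < 0.5 else "-")

    gi = 0
    for _ in range(n_genes_c1):
        plant_gene(chrom_names[0], cur1, gi)
        gi += 1

    n_scatter = sum(te_budget.values())
    n_scatter_c1 = n_scatter if params.n_chroms == 1 else int(round(n_scatter * 0.65))
    for _ in range(n_scatter_c1):
        start, _ = cur1.take(params.te_consensus_len, int(rng.integers(4_000, 9_000)))
        plant_te(chrom_names[0], start, next_family(), "+" if rng.random() < 0.5 else "-")

    # --- remaining chromosomes: genes + scattered TEs ---------------------
    for ci in range(1, params.n_chroms):
        cur = _Cursor(chrom_names[ci], int(sizes[ci]))
        n_genes_here = (params.n_genes - gi) // (params.n_chroms - ci)
        for _ in range(n_genes_here):
            plant_gene(chrom_names[ci], cur, gi)
            gi += 1
        n_scatter_here = sum(te_budget.values()) // (params.n_chroms - ci)
        for _ in range(n_scatter_here):
            start, _ = cur.take(params.te_consensus_len, int(rng.integers(4_000, 9_000)))
            plant_te(chrom_names[ci], start, next_family(), "+" if rng.random() < 0.5 else "-")

    # --- FPKM table -------------------------------------------------------
    tx_ids = [m.transcript_id for m in gene_models]
    datasets = ["RNAseq_E11", "RNAseq_E14"]
    values = np.zeros((len(tx_ids), len(datasets)))
    for i in range(len(tx_ids)):
        expressed = i % 10 < 7
        for j in range(len(datasets)):
            if expressed:
                values[i, j] = round(1.0 + float(rng.lognormal(1.0, 0.8)), 2)
            else:
                values[i, j] = round(float(rng.uniform(0.0, 0.9)), 2)
    fpkm = pd.DataFrame(values, index=pd.Index(tx_ids, name="transcript_id"), columns=datasets)
    if len(tx_ids) >= 2:  # post-condition: both expression classes present
        if (fpkm.max(axis=1) >= 1).all():
            fpkm.iloc[-1] = 0.5
        if (fpkm.max(axis=1) < 1).all():
            fpkm.iloc[0] = 2.0

    bundle = ReferenceBundle(
        genome={name: "".join(arr) for name, arr in genome.items()},
        te_features=sorted(te_features, key=lambda t: (t.chrom, t.start)),
        gene_models=sorted(gene_models, key=lambda m: (m.chrom, m.start)),
        ncrna_loci=ncrna_loci,
        fpkm_table=fpkm,
        te_consensus=consensus,
    )
    _check_bounds(bundle)
    return bundle


def _check_bounds(bundle: ReferenceBundle) -> None:
    for t in bundle.te_features:
        if t.start < 0 or t.end > len(bundle.genome[t.chrom]):
            raise ValueError(f"TE outside chromosome bounds: {t}")
    for m in bundle.gene_models:
        if m.start < 0 or m.end > len(bundle.genome[m.chrom]):
            raise ValueError(f"gene outside chromosome bounds: {m.transcript_id}")
    for n in bundle.ncrna_loci:
        if n.start < 0 or n.end > len(bundle.genome[n.chrom]):
            raise ValueError(f"ncRNA locus outside chromosome bounds: {n.name}")


# ---------------------------------------------------------------------------
# default planted-cluster layout

#: stage emission weights mimicking the TE-heavy -> intergenic-heavy trend
#: across germline development
TE_CLUSTER_WEIGHTS = {"BC": 1.0, "PGC": 0.5, "E11G": 0.25, "E14G": 0.2, "AT": 0.06}
GENIC_CLUSTER_WEIGHTS = {"BC": 0.1, "PGC": 0.4, "E11G": 0.6, "E14G": 0.65, "AT": 0.2}
INTERGENIC_CLUSTER_WEIGHTS = {"BC": 0.05, "PGC": 0.3, "E11G": 0.45, "E14G": 0.5, "AT": 1.0}

_MODE_CYCLE = ("mono_plus", "mono_minus", "bidirectional", "dual_strand")


def te_blocks(bundle: ReferenceBundle, max_intra_gap: int = 500, min_copies: int = 2) -> list[tuple[str, int, int]]:
    """Spans of runs of nearby TE copies (the planted TE-dense blocks)."""
    blocks = []
    tes = sorted(bundle.te_features, key=lambda t: (t.chrom, t.start))
    run: list[TEFeature] = []
    for t in tes:
        if run and t.chrom == run[-1].chrom and t.start - run[-1].end <= max_intra_gap:
            run.append(t)
        else:
            if len(run) >= min_copies:
                blocks.append((run[0].chrom, run[0].start, run[-1].end))
            run = [t]
    if len(run) >= min_copies:
        blocks.append((run[0].chrom, run[0].start, run[-1].end))
    return blocks


def intergenic_windows(
    bundle: ReferenceBundle, n: int = 4, window: int = 4000, margin: int = 8000, spacing: int = 20_000
) -> list[tuple[str, int, int]]:
    """Annotation-free windows inside large intergenic gaps."""
    feats: dict[str, list[tuple[int, int]]] = {c: [] for c in bundle.genome}
    for t in bundle.te_features:
        feats[t.chrom].append((t.start, t.end))
    for m in bundle.gene_models:
        feats[m.chrom].append((m.start, m.end))
    for x in bundle.ncrna_loci:
        feats[x.chrom].append((x.start, x.end))
    out = []
    for chrom in sorted(bundle.genome):
        ivs = sorted(feats[chrom])
        edges = [(0, 0)] + ivs + [(len(bundle.genome[chrom]), len(bundle.genome[chrom]))]
        prev_end = 0
        for s, e in edges[1:]:
            gap = s - prev_end
            if gap >= window + 2 * margin:
                pos = prev_end + margin
                while pos + window + margin <= s and len(out) < n:
                    out.append((chrom, pos, pos + window))
                    pos += window + spacing
            prev_end = max(prev_end, e)
            if len(out) >= n:
                return out
    return out


def default_cluster_specs(bundle: ReferenceBundle, base_n: int = 40_000) -> list[ClusterSpec]:
    """The default 12-cluster layout: 4 TE-dense, 4 genic, 4 intergenic."""
    specs: list[ClusterSpec] = []
    blocks = te_blocks(bundle)[:4]
    for i, (chrom, s, e) in enumerate(blocks):
        mode = _MODE_CYCLE[i % 4]
        specs.append(
            ClusterSpec(
                chrom, s, e, mode, TE_CLUSTER_WEIGHTS, base_n,
                pingpong_frac=0.2 if mode == "dual_strand" else 0.08,
                name=f"te_cluster{i + 1}",
            )
        )
    te_chroms = {(t.chrom, t.start, t.end) for t in bundle.te_features}

    def has_embedded_te(m: GeneModel) -> bool:
        return any(c == m.chrom and s < m.end and e > m.start for c, s, e in te_chroms)

    clean_genes = [
        m for m in bundle.gene_models if m.end - m.start >= 2000 and not has_embedded_te(m)
    ]
    clean_genes.sort(key=lambda m: (-(m.end - m.start), m.transcript_id))
    for i, m in enumerate(clean_genes[:4]):
        mode = _MODE_CYCLE[(i + 1) % 4]
        specs.append(
            ClusterSpec(
                m.chrom, m.start, m.end, mode, GENIC_CLUSTER_WEIGHTS, base_n,
                pingpong_frac=0.2 if mode == "dual_strand" else 0.08,
                name=f"genic_cluster{i + 1}",
            )
        )
    for i, (chrom, s, e) in enumerate(intergenic_windows(bundle, n=4)):
        mode = _MODE_CYCLE[(i + 2) % 4]
        specs.append(
            ClusterSpec(
                chrom, s, e, mode, INTERGENIC_CLUSTER_WEIGHTS, base_n,
                pingpong_frac=0.2 if mode == "dual_strand" else 0.08,
                name=f"intergenic_cluster{i + 1}",
            )
        )
    return specs


# ---------------------------------------------------------------------------
# read emission


def _draw_lengths(rng, n, mean, sd, lo=24, hi=34):
    return np.clip(np.rint(rng.normal(mean, sd, n)), lo, hi).astype(int)


def _position_pools(g: np.ndarray, spec: ClusterSpec):
    """5'-position pools by (strand, 1U) inside the cluster span.

    Plus-strand 5' positions x must leave room rightward (x + 34 <= end);
    minus-strand 5' positions p extend leftward (p - 33 >= start).  A
    plus read starting at x has 1U iff genome[x] == T; a minus read with
    5' at p has 1U iff genome[p] == A (its first base is the complement).
    """
    plus_lo, plus_hi = spec.start, spec.end - 34
    minus_lo, minus_hi = spec.start + 33, spec.end - 1
    xs = np.arange(plus_lo, plus_hi)
    ps = np.arange(minus_lo, minus_hi + 1)
    pools = {
        ("+", True): xs[g[xs] == T],
        ("+", False): xs[g[xs] != T],
        ("-", True): ps[g[ps] == A],
        ("-", False): ps[g[ps] != A],
    }
    mid = (spec.start + spec.end) // 2
    return pools, mid


def _emit_cluster_reads(
    rng: np.random.Generator,
    chrom_seq: str,
    g: np.ndarray,
    spec: ClusterSpec,
    n: int,
) -> list[tuple[int, int, str, str]]:
    """Emit ``n`` reads from one cluster: (start, end, strand, sequence)."""
    reads: list[tuple[int, int, str, str]] = []
    n_pairs = int(round(n * spec.pingpong_frac)) // 2
    n_single = n - 2 * n_pairs

    if n_pairs:
        lo, hi = spec.start + 40, spec.end - 50
        win = np.arange(lo, hi)
        anchors = win[(g[win] == T) & (g[win + 9] == A)]
        if anchors.size == 0:
            raise ValueError(f"no ping-pong anchor sites in cluster {spec.label}")
        xs = rng.choice(anchors, n_pairs)
        l1 = _draw_lengths(rng, n_pairs, spec.length_mean, spec.length_sd)
        l2 = _draw_lengths(rng, n_pairs, spec.length_mean, spec.length_sd)
        for x, a, b in zip(xs.tolist(), l1.tolist(), l2.tolist()):
            reads.append((x, x + a, "+", chrom_seq[x : x + a]))
            s2 = x + 10 - b
            reads.append((s2, x + 10, "-", revcomp(chrom_seq[s2 : x + 10])))

    if n_single:
        pools, mid = _position_pools(g, spec)
        if spec.mode == "bidirectional":
            # divergent arms: minus arm left of the midpoint, plus arm right
            for key in list(pools):
                strand, _u1 = key
                pool = pools[key]
                sided = pool[pool < mid] if strand == "-" else pool[pool >= mid]
                if sided.size:
                    pools[key] = sided
        if spec.mode == "mono_plus":
            strands = np.full(n_single, "+")
        elif spec.mode == "mono_minus":
            strands = np.full(n_single, "-")
        else:
            strands = np.where(rng.random(n_single) < 0.5, "-", "+")
        is_u1 = rng.random(n_single) < spec.u1_prob
        lengths = _draw_lengths(rng, n_single, spec.length_mean, spec.length_sd)
        for strand, u1 in (("+", True), ("+", False), ("-", True), ("-", False)):
            sel = (strands == strand) & (is_u1 == u1)
            k = int(sel.sum())
            if k == 0:
                continue
            pool = pools[(strand, u1)]
            if pool.size == 0:  # degenerate region: fall back across 1U class
                pool = pools[(strand, not u1)]
            ps = pool[rng.integers(0, pool.size, k)]
            for p, L in zip(ps.tolist(), lengths[sel].tolist()):
                if strand == "+":
                    reads.append((p, p + L, "+", chrom_seq[p : p + L]))
                else:
                    reads.append((p - L + 1, p + 1, "-", revcomp(chrom_seq[p - L + 1 : p + 1])))
    return reads


def simulate_sample(
    bundle: ReferenceBundle,
    cluster_specs: Sequence[ClusterSpec],
    stage: str,
    noise: NoiseSpec | None = None,
    adaptor: str | None = DEFAULT_ADAPTOR,
    seed: int = 0,
    sample_id: str | None = None,
) -> tuple[list[tuple[str, str]], TruthManifest]:
    """Simulate one oxidised small RNA-seq sample.

    Returns FASTQ-ready ``(read_id, sequence)`` records (adaptor already
    appended when given) and the sample's ground-truth manifest.  Cluster
    emission is ``round(n_reads * stage_weights[stage])`` per spec; ping-
    pong pairs sit on opposite strands with 5' ends exactly 9 nt apart and
    adenine at partner position 10; contaminants and uniform degradation
    reads are added per ``noise``.
    """
    noise = noise or NoiseSpec()
    sample_id = sample_id or stage
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    rows: list[tuple] = []
    genome_bytes = {c: as_bytes(s) for c, s in bundle.genome.items()}

    for spec in cluster_specs:
        if stage not in spec.stage_weights:
            raise ValueError(f"stage {stage!r} missing from cluster {spec.label} weights")
        if spec.chrom not in bundle.genome:
            raise ValueError(f"cluster {spec.label} on unknown chromosome {spec.chrom!r}")
        if spec.end > len(bundle.genome[spec.chrom]) or spec.start < 0:
            raise ValueError(f"cluster {spec.label} outside the genome")
        n = int(round(spec.n_reads * spec.stage_weights[stage]))
        if n == 0:
            continue
        emitted = _emit_cluster_reads(
            rng, bundle.genome[spec.chrom], genome_bytes[spec.chrom], spec, n
        )
        for s, e, strand, seq in emitted:
            rows.append((spec.chrom, s, e, strand, seq, "piRNA_cluster", spec.label))

    # dispersed TE-derived piRNAs (antisense-biased against the TE strand)
    if noise.te_reads and bundle.te_features:
        n_te = len(bundle.te_features)
        picks = rng.integers(0, n_te, noise.te_reads)
        lengths = _draw_lengths(rng, noise.te_reads, 27.0, 2.0)
        anti = rng.random(noise.te_reads) < noise.te_antisense_prob
        for k in range(noise.te_reads):
            te = bundle.te_features[int(picks[k])]
            L = int(lengths[k])
            strand = _flip(te.effective_strand) if anti[k] else te.effective_strand
            s = int(rng.integers(te.start, te.end - L))
            seq = bundle.genome[te.chrom][s : s + L]
            if strand == "-":
                seq = revcomp(seq)
            rows.append((te.chrom, s, s + L, strand, seq, "piRNA_TE", te.family))

    pirna_seqs = {r[4] for r in rows}
    blob = _blacklist_blob(
        {k: v for bl in bundle.blacklists().values() for k, v in bl.items()}
    )
    ncrna_ivs = {c: [] for c in bundle.genome}
    for x in bundle.ncrna_loci:
        ncrna_ivs[x.chrom].append((x.start, x.end))

    # contaminant fragments, drawn from the ncRNA loci so they map exactly
    def emit_fragments(loci: list[NcRNALocus], count: int, cls: str, lo: int, hi: int):
        if not loci or count == 0:
            return
        picks = rng.integers(0, len(loci), count)
        for k in range(count):
            locus = loci[int(picks[k])]
            L = int(rng.integers(lo, min(hi, len(locus.sequence)) + 1))
            off = int(rng.integers(0, len(locus.sequence) - L + 1))
            seq = locus.sequence[off : off + L]
            if locus.strand == "+":
                s = locus.start + off
            else:
                s = locus.end - off - L
            rows.append((locus.chrom, s, s + L, locus.strand, seq, cls, locus.name))

    by_class: dict[str, list[NcRNALocus]] = {}
    for x in bundle.ncrna_loci:
        by_class.setdefault(x.ncrna_class, []).append(x)
    emit_fragments(by_class.get("rRNA", []), noise.rrna_frags, "rRNA_frag", 24, 34)
    emit_fragments(by_class.get("tRNA", []), noise.trna_frags, "tRNA_frag", 24, 34)
    emit_fragments(by_class.get("known_miRNA", []), noise.known_mirna, "miRNA", 18, 23)
    emit_fragments(by_class.get("predicted_miRNA", []), noise.predicted_mirna, "miRNA", 18, 23)

    # uniform genomic degradation background (separability-guarded)
    chroms = sorted(bundle.genome)
    chrom_lens = np.array([len(bundle.genome[c]) for c in chroms], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()
    for _ in range(noise.degradation):
        for _attempt in range(50):
            c = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            L = int(rng.integers(24, 35))
            s = int(rng.integers(0, len(bundle.genome[c]) - L))
            if any(s < e and s + L > b for b, e in ncrna_ivs[c]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            seq = bundle.genome[c][s : s + L]
            if strand == "-":
                seq = revcomp(seq)
            if seq in pirna_seqs or (blob and seq in blob):
                continue
            rows.append((c, s, s + L, strand, seq, "degradation", "genome"))
            break
        else:
            raise RuntimeError("could not place a separable degradation read")

    records = []
    manifest_rows = []
    for i, (chrom, s, e, strand, seq, cls, source) in enumerate(rows):
        rid = f"{sample_id}_{i:07d}"
        full = seq + adaptor if adaptor else seq
        records.append((rid, full))
        manifest_rows.append(
            (
                rid, sample_id, stage, cls, source, chrom, s, e, strand,
                e - s, seq, cls in ("piRNA_cluster", "piRNA_TE", "degradation"),
            )
        )
    manifest = TruthManifest(
        reads=pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS),
        cluster_specs=list(cluster_specs),
    )
    return records, manifest


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


# ---------------------------------------------------------------------------
# experiment-level wrapper


def simulate_experiment(
    bundle: ReferenceBundle,
    cluster_specs: Sequence[ClusterSpec],
    samples: Mapping[str, str] | None = None,
    noise: NoiseSpec | None = None,
    adaptor: str | None = DEFAULT_ADAPTOR,
    seed: int = 42,
) -> tuple[dict[str, list[tuple[str, str]]], TruthManifest]:
    """Simulate every sample of the sample sheet (sample_id -> stage)."""
    samples = samples or DEFAULT_SAMPLES
    all_records: dict[str, list[tuple[str, str]]] = {}
    manifests = []
    for i, sid in enumerate(sorted(samples)):
        child_seed = np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        records, manifest = simulate_sample(
            bundle, cluster_specs, samples[sid],
            noise=noise, adaptor=adaptor, seed=int(child_seed), sample_id=sid,
        )
        all_records[sid] = records
        manifests.append(manifest)
    return all_records, TruthManifest.concat(manifests)


def scaled_noise(scale: float) -> NoiseSpec:
    """The default noise profile scaled by ``scale`` (for small test runs)."""
    base = NoiseSpec()
    return replace(
        base,
        degradation=int(base.degradation * scale),
        te_reads=int(base.te_reads * scale),
        rrna_frags=int(base.rrna_frags * scale),
        trna_frags=int(base.trna_frags * scale),
        known_mirna=int(base.known_mirna * scale),
        predicted_mirna=int(base.predicted_mirna * scale),
    )


# ---------------------------------------------------------------------------
# truth-based evaluation


def evaluate_candidacy(manifest: TruthManifest, cands: CandidateSet) -> dict[str, float]:
    """Copy-weighted recall/precision of the candidate set vs ground truth.

    Matching is at sequence level (the pipeline collapses identical
    inserts); the generator's separability guard makes classes disjoint by
    sequence, so the comparison is exact.
    """
    truth = manifest.for_sample(cands.sample_id)
    expected = truth[truth["expected_candidate"]]["sequence"].value_counts()
    observed = pd.Series({r.sequence: r.copies for r in cands.reads}, dtype=float)
    joined = pd.concat(
        [expected.rename("exp"), observed.rename("obs")], axis=1
    ).fillna(0.0)
    matched = joined.min(axis=1).sum()
    return {
        "recall": matched / joined["exp"].sum() if joined["exp"].sum() else float("nan"),
        "precision": matched / joined["obs"].sum() if joined["obs"].sum() else float("nan"),
        "expected_copies": float(joined["exp"].sum()),
        "observed_copies": float(joined["obs"].sum()),
    }


def expected_filter_removals(manifest: TruthManifest, sample_id: str) -> dict[str, int]:
    """Planted contaminant copies per cascade step (truth-side tally)."""
    t = manifest.for_sample(sample_id)
    return {
        "rRNA_tRNA_removed": int(t["cls"].isin(["rRNA_frag", "tRNA_frag"]).sum()),
        "known_miRNA_removed": int(
            ((t["cls"] == "miRNA") & t["source"].str.startswith("known_mir")).sum()
        ),
        "predicted_miRNA_removed": int(
            ((t["cls"] == "miRNA") & t["source"].str.startswith("pred_mir")).sum()
        ),
    }


# ---------------------------------------------------------------------------
# bundle I/O


def write_bundle(bundle: ReferenceBundle, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the reference bundle as plain-text files (round-trip safe)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "te": out / "te.bed",
        "genes": out / "genes.gtf",
        "ncrna_fa": out / "ncrna.fa",
        "ncrna_bed": out / "ncrna.bed",
        "rrna_trna": out / "rrna_trna.fa",
        "known_mirna": out / "known_mirna.fa",
        "predicted_mirna": out / "predicted_mirna.fa",
        "fpkm": out / "fpkm.tsv",
    }
    spio.write_fasta(paths["genome"], bundle.genome)
    spio.write_bed6(paths["te"], spio.te_features_to_bed(bundle.te_features))
    spio.write_gtf(paths["genes"], bundle.gene_models)
    spio.write_fasta(paths["ncrna_fa"], {x.name: x.sequence for x in bundle.ncrna_loci})
    ncrna_bed = pd.DataFrame(
        [
            (x.chrom, x.start, x.end, f"{x.ncrna_class}|{x.name}", 0, x.strand)
            for x in bundle.ncrna_loci
        ],
        columns=spio.BED6_COLUMNS,
    )
    spio.write_bed6(paths["ncrna_bed"], ncrna_bed)
    bl = bundle.blacklists()
    spio.write_fasta(paths["rrna_trna"], bl["rrna_trna"])
    spio.write_fasta(paths["known_mirna"], bl["known_mirna"])
    spio.write_fasta(paths["predicted_mirna"], bl["predicted_mirna"])
    spio.write_fpkm(paths["fpkm"], bundle.fpkm_table)
    return paths


def load_bundle(in_dir: str | os.PathLike) -> ReferenceBundle:
    src = Path(in_dir)
    genome = spio.read_fasta(src / "genome.fa")
    te = spio.bed_to_te_features(spio.read_bed6(src / "te.bed"))
    genes = spio.read_gtf(src / "genes.gtf")
    seqs = spio.read_fasta(src / "ncrna.fa")
    loci = []
    for r in spio.read_bed6(src / "ncrna.bed").itertuples(index=False):
        cls, name = str(r.name).split("|", 1)
        loci.append(
            NcRNALocus(name, cls, r.chrom, int(r.start), int(r.end), r.strand, seqs[name])
        )
    fpkm = spio.read_fpkm(src / "fpkm.tsv")
    return ReferenceBundle(
        genome=genome, te_features=te, gene_models=genes, ncrna_loci=loci, fpkm_table=fpkm
    )


def write_sample(
    records: Sequence[tuple[str, str]],
    manifest: TruthManifest,
    out_dir: str | os.PathLike,
    sample_id: str,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fq = out / f"{sample_id}.fastq"
    tsv = out / f"{sample_id}.truth.tsv"
    spio.write_fastq(fq, records)
    manifest.for_sample(sample_id).to_csv(tsv, sep="\t", index=False)
    return {"fastq": fq, "manifest": tsv}


def bundles_equal(a: ReferenceBundle, b: ReferenceBundle) -> bool:
    """Field-wise equality (used by round-trip tests)."""
    return (
        a.genome == b.genome
        and a.te_features == b.te_features
        and a.gene_models == b.gene_models
        and a.ncrna_loci == b.ncrna_loci
        and a.fpkm_table.round(4).equals(b.fpkm_table.round(4))
    )
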