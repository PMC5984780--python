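"""End-to-end orchestration: reads -> candidates -> signatures ->
association -> clusters -> targets, with all tables written as TSV/BED.

Outputs are byte-deterministic for a fixed input and seed: every table is
sorted before writing and no unordered container reaches an output path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import annotation, clusters as cl, signatures as sig, targets as tg
from .candidacy import (
    DEFAULT_ADAPTOR,
    CandidateSet,
    FilterReport,
    build_exact_index,
    candidates_to_bed,
    run_candidacy,
)
from . import io as spio
from .simulate import ReferenceBundle


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline computed."""

    samples: dict[str, CandidateSet]
    reports: dict[str, FilterReport]
    length_spectra: dict[str, pd.Series]
    compositions: dict[str, sig.CompositionMatrix]
    overlap_spectra: dict[str, pd.Series]
    pingpong_z: dict[str, float]
    association_profiles: pd.DataFrame  # category x sample
    te_profiles: dict[str, pd.DataFrame]
    clusters_by_sample: dict[str, list[cl.PiCluster]]
    registry: list[cl.MergedCluster] = field(default_factory=list)
    sample_matrix: pd.DataFrame | None = None
    stage_matrix: pd.DataFrame | None = None
    enrichment: pd.Series | None = None
    mds_coords: pd.DataFrame | None = None
    mds_fractions: list[float] = field(default_factory=list)
    clustered_fraction: dict[str, float] = field(default_factory=dict)
    target_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    top_targets: dict[str, list[str]] = field(default_factory=dict)
    differential: pd.DataFrame | None = None
    biotype_summary: dict[str, int] = field(default_factory=dict)


def run_pipeline(
    bundle: ReferenceBundle,
    reads_by_sample: Mapping[str, Sequence[tuple[str, str]] | str | Path],
    stages: Mapping[str, str],
    out_dir: str | Path | None = None,
    adaptor: str | None = DEFAULT_ADAPTOR,
    cluster_params: cl.ClusterParams | None = None,
    stage_groups: Mapping[str, Sequence[str]] | None = None,
    top_n: int = 500,
    min_target_pirpm: float = 70.0,
) -> PipelineResult:
    """Run the full analysis over all samples of one experiment.

    ``reads_by_sample`` maps sample id to either in-memory
    ``(read_id, sequence)`` records or a FASTQ path.  When ``out_dir`` is
    given every table is also written to disk.
    """
    spio.check_chromosomes(bundle.genome, (t.chrom for t in bundle.te_features), "TE annotation")
    spio.check_chromosomes(bundle.genome, (m.chrom for m in bundle.gene_models), "gene models")
    index = build_exact_index(bundle.genome)
    blacklists = bundle.blacklists()
    feat_index = annotation.FeatureIndex(bundle.te_features, bundle.gene_models)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    res = PipelineResult(
        samples={}, reports={}, length_spectra={}, compositions={},
        overlap_spectra={}, pingpong_z={}, association_profiles=pd.DataFrame(),
        te_profiles={}, clusters_by_sample={},
    )
    profiles = {}
    for sid in sorted(reads_by_sample):
        raw = reads_by_sample[sid]
        if isinstance(raw, (str, Path)):
            seqs = [s for _, s in spio.read_fastq(raw)]
        else:
            seqs = [s for _, s in raw]
        cands, report = run_candidacy(
            seqs, index, blacklists, sample_id=sid, stage=stages[sid], adaptor=adaptor
        )
        res.samples[sid] = cands
        res.reports[sid] = report
        res.length_spectra[sid] = sig.length_spectrum(cands)
        res.compositions[sid] = sig.positional_composition(cands.reads)
        spectrum = sig.overlap_spectrum(cands)
        res.overlap_spectra[sid] = spectrum
        res.pingpong_z[sid] = sig.pingpong_enrichment(spectrum)
        profiles[sid] = annotation.association_profile(cands, feat_index)
        res.te_profiles[sid] = annotation.te_family_profile(cands, feat_index)
        res.clusters_by_sample[sid] = cl.detect_clusters(cands, cluster_params)
        if out is not None:
            candidates_to_bed(cands).to_csv(out / f"{sid}.candidates.bed", sep="\t", header=False, index=False)
            report.to_frame().to_csv(out / f"{sid}.filter_report.tsv", sep="\t", index=False)
            res.length_spectra[sid].rename_axis("length").to_csv(out / f"{sid}.length_spectrum.tsv", sep="\t")
            res.compositions[sid].freq.rename_axis("position").to_csv(out / f"{sid}.composition.tsv", sep="\t")
            spectrum.to_csv(out / f"{sid}.overlap_spectrum.tsv", sep="\t")
            profiles[sid].rename_axis("category").to_csv(out / f"{sid}.association_profile.tsv", sep="\t")
            res.te_profiles[sid].to_csv(out / f"{sid}.te_family_profile.tsv", sep="\t")
            spio.write_bed6(out / f"{sid}.clusters.bed", cl.clusters_to_bed(res.clusters_by_sample[sid]))
            try:
                pp = sig.pingpong_subset_composition(cands)
                pp.freq.rename_axis("position").to_csv(out / f"{sid}.pingpong_composition.tsv", sep="\t")
            except sig.EmptySubsetError:
                (out / f"{sid}.pingpong_composition.tsv").write_text("# no reads pairable at overlap 10\n")
    res.association_profiles = pd.DataFrame(profiles)[sorted(profiles)]

    # --- cross-sample cluster registry -----------------------------------
    res.registry = cl.merge_clusters(res.clusters_by_sample.values())
    res.registry = cl.extend_by_transcripts(res.registry, bundle.gene_models, bundle.fpkm_table)
    res.sample_matrix, res.stage_matrix = cl.quantify_pirpkm(res.registry, res.samples, stage_groups)
    res.enrichment = cl.classify_stage_enrichment(res.stage_matrix)
    for sid, cands in res.samples.items():
        res.clustered_fraction[sid] = (
            cl.clusterable_copies(res.registry, cands) / cands.denom if cands.denom else float("nan")
        )
    if len(res.samples) >= 3:
        res.mds_coords, fractions = cl.mds_embedding(res.sample_matrix)
        res.mds_fractions = [float(f) for f in fractions]

    # --- piRNA-associated transcripts ------------------------------------
    for sid, cands in res.samples.items():
        table = tg.transcript_association(cands, bundle.gene_models, bundle.te_features)
        res.target_tables[sid] = table
        res.top_targets[sid] = tg.select_top_targets(table, n=top_n, min_pirpm=min_target_pirpm)
    eg_samples = sorted(s for s, st in stages.items() if st in ("E11G", "E14G"))
    if len(eg_samples) >= 2:
        s1, s2 = eg_samples[0], eg_samples[-1]
        union = tg.stage_union(
            {s1: res.top_targets[s1], s2: res.top_targets[s2]}
        )
        res.differential = tg.differential_association(
            res.target_tables[s1], res.target_tables[s2]
        )
        res.biotype_summary = tg.biotype_breakdown(list(union.index), bundle.gene_models)

    if out is not None:
        spio.write_bed6(out / "merged_clusters.bed", cl.registry_to_bed(res.registry))
        res.sample_matrix.rename_axis("cluster_id").to_csv(out / "sample_matrix.tsv", sep="\t")
        res.stage_matrix.rename_axis("cluster_id").to_csv(out / "stage_matrix.tsv", sep="\t")
        res.enrichment.rename_axis("cluster_id").to_csv(out / "enrichment_labels.tsv", sep="\t")
        if res.mds_coords is not None:
            res.mds_coords.rename_axis("sample").to_csv(out / "mds_coordinates.tsv", sep="\t")
        for sid in sorted(res.target_tables):
            res.target_tables[sid].to_csv(out / f"{sid}.transcript_association.tsv", sep="\t")
            pd.Series(res.top_targets[sid], name="transcript_id").to_csv(
                out / f"{sid}.top_targets.tsv", sep="\t", index=False
            )
        if res.differential is not None:
            res.differential.to_csv(out / "differential_association.tsv", sep="\t")
        summary = {
            "pingpong_z": res.pingpong_z,
            "clustered_fraction": res.clustered_fraction,
            "n_merged_clusters": len(res.registry),
            "enrichment_counts": res.enrichment.value_counts().sort_index().to_dict(),
            "mds_eigenvalue_fractions": res.mds_fractions,
            "biotype_summary": res.biotype_summary,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return res
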