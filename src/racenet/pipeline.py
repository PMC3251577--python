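"""End-to-end synthetic pipeline: simulate -> pool -> call -> filter ->
assign -> network, with recovery metrics against the planted truth.

This is the orchestration layer used by tests and the command line; each
stage is the corresponding library function with scaled-down default
geometry (two 120 kb chromosomes, 20 genes, pooling clearances scaled to
match), chosen so a full run takes seconds while still exercising every
constraint the genome-scale design does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import assignment as asg
from . import calling, filters, network, pooling, simulate
from .core import project_exons

__all__ = ["PipelineConfig", "PipelineResult", "default_network_spec", "run_pipeline"]


@dataclass
class PipelineConfig:
    n_chroms: int = 2
    chrom_len_nt: int = 120_000
    n_genes: int = 20
    isoform_rate: float = 0.5
    samples: tuple[str, ...] = ("brain", "testis", "liver", "k562")
    pooling: pooling.PoolingConfig = field(
        default_factory=lambda: pooling.PoolingConfig(L=40_000, l=4_000)
    )
    caller: calling.CallerParams = field(
        default_factory=lambda: calling.CallerParams(I=95.0, M=50, m=3, c="middle")
    )
    noise: simulate.NoiseConfig = field(default_factory=simulate.NoiseConfig)
    run_uspp_filter: bool = True


def default_network_spec(ann: simulate.SyntheticAnnotation, samples) -> simulate.NetworkSpec:
    """A representative planted network: adjacent-gene reciprocal pairs, a
    3-clique and a hub, all within chimera-reachable distances."""
    by_chrom: dict[str, list[str]] = {}
    for g in ann.genes:
        by_chrom.setdefault(g.locus.chrom, []).append(g.gene_id)
    chroms = sorted(by_chrom)
    c1 = by_chrom[chroms[0]]
    c2 = by_chrom[chroms[-1]] if len(chroms) > 1 else c1
    pairs = [(c1[0], c1[1]), (c1[4], c1[5]), (c2[0], c2[1])]
    clique = tuple(c1[6:9])
    hub = {c2[4]: 3}
    return simulate.NetworkSpec(
        samples=tuple(samples),
        reciprocal_pairs=tuple(pairs),
        cliques=(clique,),
        hubs=hub,
        presence_rate=0.5,
        max_partner_gap=30_000,
    )


@dataclass
class PipelineResult:
    ann: simulate.SyntheticAnnotation
    truth: simulate.TruthTable
    pools: list
    tracks: dict
    frags: list
    filter_report: filters.FilterReport
    assignments: list
    discarded: list
    graph: network.ConnectionGraph
    reciprocal: dict
    recovered_fraction: float
    spurious_fraction: float
    acs_table: object


def run_pipeline(
    seed: int = 0,
    config: PipelineConfig | None = None,
    network_spec: simulate.NetworkSpec | None = None,
) -> PipelineResult:
    """Run the full synthetic pipeline and score edge recovery.

    ``recovered_fraction`` is the share of planted reciprocal gene pairs
    recovered as reciprocal connections; ``spurious_fraction`` is the
    share of recovered reciprocal pairs that were not planted.
    """
    cfg = config or PipelineConfig()
    ann = simulate.generate_annotation(
        n_chroms=cfg.n_chroms,
        chrom_len_nt=cfg.chrom_len_nt,
        n_genes=cfg.n_genes,
        isoform_rate=cfg.isoform_rate,
        seed=seed,
    )
    spec = network_spec or default_network_spec(ann, cfg.samples)
    truth = simulate.plant_transcriptome(ann, spec, seed=seed + 1)

    _per_chrom, k = pooling.min_pool_count(ann.primers, cfg.pooling)
    pools = pooling.assign_pools(ann.primers, k, cfg.pooling)
    pool_members = {p.pool_id: set(p.primer_ids) for p in pools}

    tracks, negatives = simulate.simulate_array_tracks(
        truth, ann, pools, samples=cfg.samples, noise=cfg.noise, seed=seed + 2
    )

    flagged = filters.flag_unspecific_probes(ann.probes, ann.genome)
    specific_mask = (~flagged["unspecific"]).to_numpy()

    frags = []
    for key, track in tracks.items():
        frags.extend(
            calling.call_racefrags(track, cfg.caller, specific_probes=specific_mask, experiment=key)
        )
    negative_frags = []
    for sample, track in negatives.items():
        negative_frags.extend(
            calling.call_racefrags(
                track, calling.NEGATIVE_CONTROL_PARAMS, specific_probes=specific_mask
            )
        )

    report = filters.FilterReport(n_input=len(frags))
    if cfg.run_uspp_filter:
        templates = [
            filters.TranscriptTemplate(
                transcript_id=f"{g.gene_id}.t{i + 1}", gene_id=g.gene_id, exons=tuple(tx)
            )
            for g in ann.genes
            for i, tx in enumerate(g.transcripts)
        ]
        spps = filters.simulate_racearray(templates, ann.primers, ann.probes, ann.genome)
        frags, report = filters.apply_uspp_filter(frags, spps, pool_members, report)
    frags, report = filters.apply_negative_control_filter(frags, negative_frags, report)

    assignments, discarded = asg.assign_racefrags(frags, pool_members, ann.primers)
    acs_table = asg.compute_acs(frags, assignments)
    graph = network.build_graph(assignments, ann.genes, ann.primers)
    recip = network.reciprocal_connections(graph)

    planted = truth.reciprocal_pairs()
    recovered = {
        tuple(sorted((row.gene_a, row.gene_b))) for row in recip["pairs"].itertuples()
    }
    recovered_fraction = (
        len(planted & recovered) / len(planted) if planted else float("nan")
    )
    spurious_fraction = (
        len(recovered - planted) / len(recovered) if recovered else 0.0
    )
    return PipelineResult(
        ann=ann,
        truth=truth,
        pools=pools,
        tracks=tracks,
        frags=frags,
        filter_report=report,
        assignments=assignments,
        discarded=discarded,
        graph=graph,
        reciprocal=recip,
        recovered_fraction=recovered_fraction,
        spurious_fraction=spurious_fraction,
        acs_table=acs_table,
    )


def internal_projected_exons(ann: simulate.SyntheticAnnotation):
    """Internal-class projected exon segments across all genes (the
    reference set for exonic accuracy)."""
    out = []
    for g in ann.genes:
        pes = project_exons(g)
        for seg, cls in zip(pes.segments, pes.classes):
            if "internal" in cls:
                out.append(seg)
    return out
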