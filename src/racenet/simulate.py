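"""Synthetic RACE-array worlds with planted ground truth.

Generates toy genomes with multi-isoform gene models, 25-mer probes tiled
at 17-nt spacing, RACE primers inside ACEPs, per-experiment intensity
tracks with planted chimeric signal plus noise and cross-hybridization,
negative-control tracks driven by abundant untargeted transcripts,
expression matrices with planted correlation structure, 5C pairs enriched
for connected genes, mixture count series with linear/quadratic decay
components, and RT-PCR-like product sequences with planted junction
duplications.  Everything is deterministic given a seed, and every planted
feature is recorded in a :class:`TruthTable` so downstream stages can be
tested against known truth.

Geometry is scaled down (chromosomes of ~10^5 nt rather than ~10^7) with
pooling distance constraints scaled proportionally, so pooling, calling,
filtering and assignment are all exercised without genome-scale data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, meld_intervals
from .pooling import PoolingConfig, RacePrimer
from .validation import FiveCPair, JunctionBlocks, MixtureLibrary

__all__ = [
    "NoiseConfig",
    "NetworkSpec",
    "AuxConfig",
    "DupConfig",
    "TruthTable",
    "PlantedChimera",
    "SyntheticAnnotation",
    "ConfigurationError",
    "generate_annotation",
    "plant_transcriptome",
    "simulate_array_tracks",
    "simulate_aux_data",
    "generate_products",
]

PROBE_LEN = 25
PROBE_STEP = 17


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseConfig:
    """Array noise model: log-normal background (parameters on the log
    scale), additive signal amplitude on the linear scale, and a per-probe
    cross-hybridization rate."""

    bg_log_mean: float = 0.0
    bg_log_sd: float = 1.0
    amplitude: float = 30.0
    xhyb_rate: float = 0.002
    n_abundant_per_sample: int = 1
    abundant_len: int = 1200

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 <= self.xhyb_rate <= 1:
            raise ValueError("xhyb_rate must be in [0,1]")


@dataclass
class SyntheticAnnotation:
    """A generated world: genome, gene models, primers and probe layout."""

    genome: dict[str, str]
    genes: list[GeneModel]
    primers: list[RacePrimer]
    probes: pd.DataFrame  # probe_id, chrom, start, end
    planted_multimap_probes: list[str] = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def generate_annotation(
    n_chroms: int = 2,
    chrom_len_nt: int = 120_000,
    n_genes: int = 20,
    isoform_rate: float = 0.5,
    seed: int = 0,
    n_exons: tuple[int, int] = (3, 5),
    exon_len: tuple[int, int] = (140, 200),
    intron_len: tuple[int, int] = (250, 500),
    multi_probe_rate: float = 0.07,
) -> SyntheticAnnotation:
    """Generate a toy genome, non-overlapping gene models, RACE primers
    (one 5' and one 3' per gene, placed inside ACEPs) and the tiled probe
    layout.

    Probes are 25-mers every 17 nt; about ``multi_probe_rate`` of them are
    made multi-mapping by copying their sequence into an intergenic
    location elsewhere.  Raises :class:`ConfigurationError` when the
    requested genes do not fit.
    """
    if chrom_len_nt < 10_000:
        raise ConfigurationError("chromosomes must be >= 10 kb")
    rng = np.random.default_rng(seed)
    genome = {f"chr{i + 1}": _random_seq(rng, chrom_len_nt) for i in range(n_chroms)}
    chroms = list(genome)

    genes: list[GeneModel] = []
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    max_span = n_exons[1] * exon_len[1] + (n_exons[1] - 1) * intron_len[1]
    gi = 0
    for ci, chrom in enumerate(chroms):
        k = per_chrom[ci]
        if k == 0:
            continue
        slot = chrom_len_nt // k
        if slot < max_span + 2_000:
            raise ConfigurationError(
                f"{k} genes of up to {max_span} nt do not fit on a {chrom_len_nt} nt chromosome"
            )
        for j in range(k):
            gi += 1
            gene_id = f"g{gi:03d}"
            strand = "+" if gi % 2 else "-"
            anchor = j * slot + int(rng.integers(500, 1_500))
            ne = int(rng.integers(n_exons[0], n_exons[1] + 1))
            exons = []
            pos = anchor
            for _ in range(ne):
                el = int(rng.integers(exon_len[0], exon_len[1] + 1))
                exons.append(GenomicInterval(chrom, pos, pos + el, strand))
                pos += el + int(rng.integers(intron_len[0], intron_len[1] + 1))
            locus = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
            transcripts = [list(exons)]
            coding = [list(exons)]
            if ne >= 3 and rng.random() < isoform_rate:
                skip = int(rng.integers(1, ne - 1))  # drop one internal exon
                iso = [e for i, e in enumerate(exons) if i != skip]
                transcripts.append(iso)
                coding.append(list(iso))
            genes.append(
                GeneModel(gene_id=gene_id, locus=locus, transcripts=transcripts, coding_spans=coding)
            )

    from .core import project_exons

    primers: list[RacePrimer] = []
    for g in genes:
        pes = project_exons(g)
        usable = [a for a in pes.aceps if len(a) >= PROBE_LEN + 10]
        if not usable:
            raise ConfigurationError(f"{g.gene_id}: no ACEP can host a 25-nt primer")
        ordered = usable if g.strand == "+" else list(reversed(usable))
        for race_type, acep in (("5p", ordered[-1]), ("3p", ordered[0])):
            off = (len(acep) - PROBE_LEN) // 2
            span = GenomicInterval(acep.chrom, acep.start + off, acep.start + off + PROBE_LEN, g.strand)
            primers.append(
                RacePrimer(
                    primer_id=f"{g.gene_id}_{race_type}", gene_id=g.gene_id,
                    span=span, race_type=race_type,
                )
            )

    rows = []
    pid = 0
    for chrom in chroms:
        for start in range(0, chrom_len_nt - PROBE_LEN + 1, PROBE_STEP):
            pid += 1
            rows.append({"probe_id": f"p{pid:06d}", "chrom": chrom, "start": start,
                         "end": start + PROBE_LEN})
    probes = pd.DataFrame(rows)

    # plant multi-mapping probes: copy their 25-mer into intergenic space.
    # Probes overlapping ACEPs are exempt, mirroring the genome-wide
    # uniqueness screen applied to primer-hosting regions in the design.
    gene_ivs = [g.locus for g in genes]
    acep_ivs = [a for g in genes for a in project_exons(g).aceps]
    p_chrom = probes["chrom"].to_numpy()
    p_start = probes["start"].to_numpy(int)
    p_end = probes["end"].to_numpy(int)
    in_acep = np.zeros(len(probes), bool)
    for a in acep_ivs:
        in_acep |= (p_chrom == a.chrom) & (p_start < a.end) & (p_end > a.start)
    candidate_idx = np.nonzero(~in_acep)[0]
    n_multi = min(int(round(multi_probe_rate * len(probes))), len(candidate_idx))
    multi_ids: list[str] = []
    chosen = rng.choice(candidate_idx, size=n_multi, replace=False) if n_multi else []
    # protect the chosen source 25-mers and every written copy from being
    # overwritten by a later copy, which would destroy the planted duplicate
    protected = [
        GenomicInterval(probes["chrom"].iat[int(i)], int(probes["start"].iat[int(i)]),
                        int(probes["end"].iat[int(i)]))
        for i in chosen
    ]
    for idx in np.sort(chosen):
        row = probes.iloc[int(idx)]
        src = genome[row["chrom"]][int(row["start"]) : int(row["end"])]
        for _try in range(50):
            tc = chroms[int(rng.integers(0, n_chroms))]
            tpos = int(rng.integers(0, chrom_len_nt - PROBE_LEN))
            tiv = GenomicInterval(tc, tpos, tpos + PROBE_LEN)
            if any(tiv.overlaps(giv) for giv in gene_ivs) or any(
                tiv.overlaps(pv) for pv in protected
            ):
                continue
            genome[tc] = genome[tc][:tpos] + src + genome[tc][tpos + PROBE_LEN:]
            protected.append(tiv)
            multi_ids.append(row["probe_id"])
            break
    return SyntheticAnnotation(
        genome=genome, genes=genes, primers=primers, probes=probes,
        planted_multimap_probes=multi_ids,
    )


# ---------------------------------------------------------------------------
# Transcriptome planting


@dataclass(frozen=True)
class NetworkSpec:
    """Which gene-gene connections to plant, and where.

    ``reciprocal_pairs`` are planted in both directions; ``cliques`` expand
    to all pairwise reciprocal connections; ``hubs`` maps a gene to a
    target reciprocal degree (partners are drawn from nearby genes).  Each
    planted undirected pair is present in a random subset of ``samples``
    (at least one; each additional sample with probability
    ``presence_rate``), and pure reciprocity is planted by construction
    (both directions share the sample set).
    """

    samples: tuple[str, ...]
    reciprocal_pairs: tuple[tuple[str, str], ...] = ()
    cliques: tuple[tuple[str, ...], ...] = ()
    hubs: dict[str, int] = field(default_factory=dict)
    presence_rate: float = 0.5
    max_partner_gap: int = 25_000


@dataclass(frozen=True)
class PlantedChimera:
    """One directed planted connection: a chimeric transcript read out by
    one primer of the index gene, covering exons of the target gene."""

    gene_from: str
    gene_to: str
    samples: frozenset
    primer_id: str
    source_exons: tuple[GenomicInterval, ...]
    target_exons: tuple[GenomicInterval, ...]


@dataclass
class TruthTable:
    """Planted ground truth for a synthetic run."""

    chimeras: list[PlantedChimera]
    network: dict[tuple[str, str], set[str]]  # directed edge -> samples
    undirected_pairs: dict[tuple[str, str], set[str]]
    hubs: list[str]
    cliques: list[tuple[str, ...]]
    junction_duplications: dict[int, int] = field(default_factory=dict)

    def reciprocal_pairs(self) -> set[tuple[str, str]]:
        return set(self.undirected_pairs)


def _pick_primer_toward(ann: SyntheticAnnotation, gene_from: GeneModel, gene_to: GeneModel):
    """The primer of gene_from whose amplification direction points at gene_to."""
    want = "+" if gene_to.locus.start >= gene_from.locus.end else "-"
    for p in ann.primers:
        if p.gene_id == gene_from.gene_id and p.amp_direction == want:
            return p
    raise ConfigurationError(f"{gene_from.gene_id}: no primer amplifies toward {gene_to.gene_id}")


def plant_transcriptome(ann: SyntheticAnnotation, spec: NetworkSpec, seed: int = 0) -> TruthTable:
    """Expand the network spec into planted chimeric transcripts.

    Every undirected pair becomes two directed chimeras (one per index
    gene) sharing a sample set, so planted reciprocity is pure.  Pairs of
    overlapping genes are rejected; hub partners are chosen among genes on
    the same chromosome within ``max_partner_gap``.
    """
    rng = np.random.default_rng(seed)
    by_id = {g.gene_id: g for g in ann.genes}
    pairs: dict[tuple[str, str], None] = {}

    def add_pair(a: str, b: str) -> None:
        if a == b:
            raise ConfigurationError(f"self-pair {a}")
        ga, gb = by_id[a], by_id[b]
        if ga.locus.overlaps(gb.locus):
            raise ConfigurationError(f"planted edge between overlapping genes {a}/{b}")
        pairs[tuple(sorted((a, b)))] = None

    for a, b in spec.reciprocal_pairs:
        add_pair(a, b)
    for clique in spec.cliques:
        members = list(clique)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                add_pair(a, b)
    for hub, degree in spec.hubs.items():
        hg = by_id[hub]
        candidates = sorted(
            (
                g.gene_id
                for g in ann.genes
                if g.gene_id != hub
                and g.locus.chrom == hg.locus.chrom
                and not g.locus.overlaps(hg.locus)
                and min(
                    abs(g.locus.start - hg.locus.end), abs(hg.locus.start - g.locus.end)
                ) <= spec.max_partner_gap
            ),
        )
        have = sum(1 for p in pairs if hub in p)
        for partner in candidates:
            if have >= degree:
                break
            key = tuple(sorted((hub, partner)))
            if key not in pairs:
                add_pair(hub, partner)
                have += 1
        if have < degree:
            raise ConfigurationError(
                f"hub {hub}: only {have} partners available within {spec.max_partner_gap} nt"
            )

    chimeras: list[PlantedChimera] = []
    network: dict[tuple[str, str], set[str]] = {}
    undirected: dict[tuple[str, str], set[str]] = {}
    for a, b in pairs:
        present = {spec.samples[int(rng.integers(0, len(spec.samples)))]}
        for s in spec.samples:
            if rng.random() < spec.presence_rate:
                present.add(s)
        undirected[(a, b)] = set(present)
        for src, dst in ((a, b), (b, a)):
            gsrc, gdst = by_id[src], by_id[dst]
            primer = _pick_primer_toward(ann, gsrc, gdst)
            src_exons = tuple(
                e for e in gsrc.transcripts[0]
                if (e.end > primer.span.start if primer.amp_direction == "+" else e.start < primer.span.end)
            )
            tgt_exons = tuple(gdst.transcripts[0][:2])
            chimeras.append(
                PlantedChimera(
                    gene_from=src, gene_to=dst, samples=frozenset(present),
                    primer_id=primer.primer_id, source_exons=src_exons, target_exons=tgt_exons,
                )
            )
            network.setdefault((src, dst), set()).update(present)
    return TruthTable(
        chimeras=chimeras,
        network=network,
        undirected_pairs=undirected,
        hubs=sorted(spec.hubs),
        cliques=tuple(tuple(c) for c in spec.cliques),
    )


# ---------------------------------------------------------------------------
# Array tracks


def _product_intervals(ann: SyntheticAnnotation, primer: RacePrimer) -> list[GenomicInterval]:
    """Genomic (exonic) footprint of the primer's own-gene RACE product:
    from the priming site to the transcript terminus in the amplification
    direction."""
    gene = ann.gene(primer.gene_id)
    out = []
    for ex in gene.transcripts[0]:
        if primer.amp_direction == "+":
            if ex.end > primer.span.start:
                out.append(GenomicInterval(ex.chrom, max(ex.start, primer.span.start), ex.end))
        else:
            if ex.start < primer.span.end:
                out.append(GenomicInterval(ex.chrom, ex.start, min(ex.end, primer.span.end)))
    return out


def simulate_array_tracks(
    truth: TruthTable,
    ann: SyntheticAnnotation,
    pools,
    samples: tuple[str, ...],
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    with_negative_controls: bool = True,
    min_probe_overlap: int = 8,
) -> tuple[dict, dict]:
    """Simulate one intensity track per (pool, sample) hybridization.

    Probe intensity = log-normal background, plus the signal amplitude at
    probes overlapping (by >= ``min_probe_overlap`` nt) a RACE product
    implied by a pooled primer -- the own-gene product plus any planted
    chimeric extension present in that sample -- plus amplitude at random
    off-target probes at the cross-hybridization rate.  Per sample, a few
    abundant untargeted intergenic transcripts light up in every track of
    that sample; negative-control tracks contain only that signal plus
    background.

    Returns ``(tracks, negative_tracks)``: experiment-keyed and
    sample-keyed DataFrames with probe_id/chrom/start/end/intensity
    columns (tracks also carry pool_id/sample_id).
    """
    rng = np.random.default_rng(seed)
    probes = ann.probes
    n = len(probes)
    starts = probes["start"].to_numpy(int)
    ends = probes["end"].to_numpy(int)
    chrom_arr = probes["chrom"].to_numpy()

    def probe_mask(ivs: list[GenomicInterval]) -> np.ndarray:
        mask = np.zeros(n, bool)
        for iv in ivs:
            ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
            mask |= (chrom_arr == iv.chrom) & (ov >= min_probe_overlap)
        return mask

    chimeras_by_primer: dict[str, list[PlantedChimera]] = {}
    for ch in truth.chimeras:
        chimeras_by_primer.setdefault(ch.primer_id, []).append(ch)

    # per-sample abundant untargeted transcripts, intergenic
    gene_ivs = [g.locus for g in ann.genes]
    abundant: dict[str, list[GenomicInterval]] = {s: [] for s in samples}
    chroms = list(ann.genome)
    for s in samples:
        for _ in range(noise.n_abundant_per_sample):
            for _try in range(100):
                c = chroms[int(rng.integers(0, len(chroms)))]
                pos = int(rng.integers(0, len(ann.genome[c]) - noise.abundant_len))
                iv = GenomicInterval(c, pos, pos + noise.abundant_len)
                if not any(iv.overlaps(g) for g in gene_ivs):
                    abundant[s].append(iv)
                    break

    primer_by_id = {p.primer_id: p for p in ann.primers}
    own_product = {p.primer_id: _product_intervals(ann, p) for p in ann.primers}

    tracks: dict = {}
    negatives: dict = {}
    base_cols = probes[["probe_id", "chrom", "start", "end"]]
    for sample in samples:
        abundant_mask = probe_mask(abundant[sample])
        for pool in pools:
            signal = np.zeros(n, float)
            for pid in pool.primer_ids:
                primer = primer_by_id[pid]
                ivs = list(own_product[pid])
                for ch in chimeras_by_primer.get(pid, ()):
                    if sample in ch.samples:
                        ivs.extend(ch.target_exons)
                signal[probe_mask(ivs)] += noise.amplitude
            signal[abundant_mask] += noise.amplitude
            if noise.xhyb_rate > 0:
                xmask = rng.random(n) < noise.xhyb_rate
                signal[xmask] += noise.amplitude
            bg = rng.lognormal(noise.bg_log_mean, noise.bg_log_sd, size=n)
            track = base_cols.copy()
            track["intensity"] = bg + signal
            track["pool_id"] = pool.pool_id
            track["sample_id"] = sample
            from .core import ExperimentKey

            tracks[ExperimentKey(pool.pool_id, sample)] = track
        if with_negative_controls:
            bg = rng.lognormal(noise.bg_log_mean, noise.bg_log_sd, size=n)
            neg = base_cols.copy()
            neg["intensity"] = bg + np.where(abundant_mask, noise.amplitude, 0.0)
            neg["pool_id"] = "NEG"
            neg["sample_id"] = sample
            negatives[sample] = neg
    return tracks, negatives


# ---------------------------------------------------------------------------
# Auxiliary data: expression, 5C, mixtures


@dataclass(frozen=True)
class AuxConfig:
    """Targets for the auxiliary generators.

    Expression: pairwise correlation ``r_connected`` for planted-connected
    gene pairs vs ``r_baseline`` for all others, induced by shared latent
    factors over ``n_expr_samples`` conditions.  5C: one scored pair per
    same-chromosome gene pair; a planted-connected pair's score is boosted
    into the top ``q_top`` percent with probability ``fivec_enrichment``.
    Mixtures: Poisson counts around N1/d biological and A1/d^2 preparation
    -artifact components, anchored at the stated d=1 values.
    """

    n_expr_samples: int = 16
    r_connected: float = 0.2
    r_baseline: float = 0.07
    fivec_enrichment: float = 0.6
    q_top: float = 10.0
    dilutions: tuple[float, ...] = (1.0, 5.0, 50.0)
    human_bio_n1: float = 2_000.0
    human_art_a1: float = 50.0
    fly_intra_n1: float = 400.0
    inter_n1: float = 800.0

    def __post_init__(self) -> None:
        if not -1 < self.r_baseline < 1 or not -1 < self.r_connected < 1:
            raise ValueError("target correlations must be in (-1, 1)")


@dataclass
class AuxData:
    expression: pd.DataFrame  # genes x expression samples
    fivec: list[FiveCPair]
    mixtures: list[MixtureLibrary]


def simulate_aux_data(
    truth: TruthTable, ann: SyntheticAnnotation, config: AuxConfig = AuxConfig(), seed: int = 0
) -> AuxData:
    """Generate the expression matrix, 5C pair table and mixture series.

    Expression uses one latent factor per planted undirected connection:
    gene profiles are a weighted sum of a global factor (loading
    sqrt(r_baseline)), its incident edge factors, and independent noise,
    normalized to unit variance, so connected pairs correlate at
    approximately ``r_connected`` and all other pairs at ``r_baseline``.
    High-degree genes cap their edge loadings to keep variances valid, so
    hub edges may sit slightly below the target.
    """
    rng = np.random.default_rng(seed)
    genes = [g.gene_id for g in ann.genes]
    idx = {g: i for i, g in enumerate(genes)}
    n, m = len(genes), config.n_expr_samples
    a2 = config.r_baseline
    edge_target = config.r_connected - config.r_baseline
    if edge_target < 0:
        raise ValueError("r_connected must be >= r_baseline")
    edges = sorted(truth.undirected_pairs)
    degree = np.zeros(n)
    for u, v in edges:
        degree[idx[u]] += 1
        degree[idx[v]] += 1
    # per-gene edge loading, capped so total variance stays below 1
    b2 = np.array(
        [min(edge_target, (1.0 - a2 - 0.05) / d) if d else 0.0 for d in degree]
    )
    g_factor = rng.standard_normal(m)
    x = np.sqrt(a2) * g_factor[None, :].repeat(n, axis=0)
    for u, v in edges:
        f = rng.standard_normal(m)
        x[idx[u]] += np.sqrt(b2[idx[u]]) * f
        x[idx[v]] += np.sqrt(b2[idx[v]]) * f
    var = a2 + degree * b2
    resid = np.sqrt(np.clip(1.0 - var, 1e-9, None))
    x += resid[:, None] * rng.standard_normal((n, m))
    expression = pd.DataFrame(
        x, index=genes, columns=[f"expr_s{i + 1}" for i in range(m)]
    )

    connected = truth.reciprocal_pairs()
    fivec: list[FiveCPair] = []
    top_lo = 1.0 - config.q_top / 100.0
    for i, ga in enumerate(ann.genes):
        for gb in ann.genes[i + 1:]:
            if ga.locus.chrom != gb.locus.chrom:
                continue
            left, right = sorted((ga.locus, gb.locus), key=lambda iv: iv.start)
            fw = GenomicInterval(left.chrom, left.start, min(left.end, left.start + 400))
            rv = GenomicInterval(right.chrom, right.start, min(right.end, right.start + 400))
            key = tuple(sorted((ga.gene_id, gb.gene_id)))
            if key in connected and rng.random() < config.fivec_enrichment:
                score = float(rng.uniform(top_lo, 1.0))
            else:
                score = float(rng.uniform(0.0, 1.0))
            fivec.append(FiveCPair(forward=fw, reverse=rv, score=score))

    mixtures = [
        MixtureLibrary(
            label="pure_human", dilution=1.0,
            intra_human=float(rng.poisson(config.human_bio_n1 + config.human_art_a1)),
            intra_fly=0.0, inter_genomic=float(rng.poisson(10.0)),
        ),
        MixtureLibrary(
            label="pure_fly", dilution=1.0, intra_human=0.0,
            intra_fly=float(rng.poisson(config.fly_intra_n1)),
            inter_genomic=float(rng.poisson(300.0)),
        ),
    ]
    for d in config.dilutions:
        mixtures.append(
            MixtureLibrary(
                label=f"mix_1to{int(d)}", dilution=d,
                intra_human=float(rng.poisson(config.human_bio_n1 / d + config.human_art_a1 / d**2)),
                intra_fly=float(rng.poisson(config.fly_intra_n1)),
                inter_genomic=float(rng.poisson(config.inter_n1 / d)),
            )
        )
    return AuxData(expression=expression, fivec=fivec, mixtures=mixtures)


# ---------------------------------------------------------------------------
# RT-PCR-like product sequences


@dataclass(frozen=True)
class DupConfig:
    """Planting of junction features in product sequences.

    With probability ``dup_rate`` a product gets a genomic junction
    duplication of length drawn from ``dup_len_range`` (inclusive);
    otherwise a canonical splice class is planted (the spec of a
    duplication overwrites the donor site region, so the two features are
    planted on disjoint products)."""

    dup_rate: float = 0.5
    dup_len_range: tuple[int, int] = (5, 10)
    splice_classes: tuple[str, ...] = ("N|GT-AG", "N|AT-AC", "non_canonical")


@dataclass(frozen=True)
class PlantedProduct:
    sequence: str
    blocks: JunctionBlocks
    splice_class: str | None
    dup_length: int


def _set_base(genome: dict[str, str], chrom: str, pos: int, base: str) -> None:
    s = genome[chrom]
    genome[chrom] = s[:pos] + base + s[pos + 1:]


def _force_mismatch(genome: dict[str, str], chrom: str, pos_edit: int, pos_ref: int) -> None:
    """Edit the base at pos_edit so it differs from the base at pos_ref."""
    ref = genome[chrom][pos_ref]
    if genome[chrom][pos_edit] == ref:
        _set_base(genome, chrom, pos_edit, {"A": "C", "C": "A", "G": "T", "T": "G"}[ref])


def generate_products(
    truth: TruthTable,
    ann: SyntheticAnnotation,
    dup_config: DupConfig = DupConfig(),
    seed: int = 0,
) -> list[PlantedProduct]:
    """Build RT-PCR-like chimeric product sequences, editing the genome
    locally so each planted feature is exact.

    For a duplication of length k the k bases following the left block are
    made identical to the first k bases of the right block (with forced
    mismatches just outside), so the duplicated k-mer flanks both sides of
    the junction in the genome while appearing once in the product.  For a
    planted splice class the implied intron's terminal dinucleotides are
    written accordingly and the flanks forced to mismatch, fixing the
    duplication length at 0.  Duplication lengths are recorded in
    ``truth.junction_duplications`` by product index.
    """
    rng = np.random.default_rng(seed)
    products: list[PlantedProduct] = []
    for ci, ch in enumerate(truth.chimeras):
        if not ch.source_exons or not ch.target_exons:
            continue
        left = max(ch.source_exons, key=lambda e: e.end)
        right = min(ch.target_exons, key=lambda e: e.start)
        if left.chrom != right.chrom or right.start - left.end < 40:
            continue
        chrom = left.chrom
        left = GenomicInterval(chrom, left.start, left.end)
        right = GenomicInterval(chrom, right.start, right.end)
        if rng.random() < dup_config.dup_rate:
            k = int(rng.integers(dup_config.dup_len_range[0], dup_config.dup_len_range[1] + 1))
            dup = ann.genome[chrom][right.start : right.start + k]
            g = ann.genome[chrom]
            ann.genome[chrom] = g[: left.end] + dup + g[left.end + k:]
            _force_mismatch(ann.genome, chrom, left.end + k, right.start + k)
            _force_mismatch(ann.genome, chrom, right.start - 1, left.end - 1)
            splice_class = None
            dup_len = k
        else:
            splice_class = dup_config.splice_classes[
                int(rng.integers(0, len(dup_config.splice_classes)))
            ]
            if splice_class == "N|GT-AG":
                donor, acceptor = "GT", "AG"
            elif splice_class == "N|AT-AC":
                donor, acceptor = "AT", "AC"
            else:
                donor, acceptor = "CC", "TT"
            _set_base(ann.genome, chrom, left.end, donor[0])
            _set_base(ann.genome, chrom, left.end + 1, donor[1])
            _set_base(ann.genome, chrom, right.start - 2, acceptor[0])
            _set_base(ann.genome, chrom, right.start - 1, acceptor[1])
            # pin the duplication length at 0 by editing exon-adjacent bases
            _force_mismatch(ann.genome, chrom, right.start, left.end)
            _force_mismatch(ann.genome, chrom, left.end - 1, right.start - 1)
            dup_len = 0
        seq = (
            ann.genome[chrom][left.start : left.end]
            + ann.genome[chrom][right.start : right.end]
        )
        blocks = JunctionBlocks(left=left, right=right, product_seq=seq)
        truth.junction_duplications[len(products)] = dup_len
        products.append(
            PlantedProduct(sequence=seq, blocks=blocks, splice_class=splice_class, dup_length=dup_len)
        )
    return products
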