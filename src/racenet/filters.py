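"""Specificity filters for called RACEfrags.

Two artifact channels are removed: (1) fragments explainable by RACE
mis-priming and/or array cross-hybridization, detected by an in-silico
RACE-array simulation run over the known transcript set (the USPP filter),
and (2) fragments explainable by highly abundant transcripts never
targeted by a RACE primer, removed by subtracting fragments called from
negative-control hybridizations of the same sample at a sensitive caller
setting.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .core import GenomicInterval, meld_intervals

__all__ = [
    "SimulatorParams",
    "TranscriptTemplate",
    "FilterReport",
    "flag_unspecific_probes",
    "simulate_racearray",
    "apply_uspp_filter",
    "apply_negative_control_filter",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulatorParams:
    """Thresholds of the in-silico RACE-array simulation.

    ``seed_len``: length in nt of the primer 3' seed that must anneal;
    ``max_mismatches``: mismatches tolerated in the seed;
    ``hyb_min_match``: minimum contiguous matching bases (out of the 25-mer
    probe) for a probe to light up on a RACE product.
    """

    seed_len: int = 15
    max_mismatches: int = 2
    hyb_min_match: int = 24

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.hyb_min_match < 1:
            raise ValueError("hyb_min_match must be >= 1")


@dataclass(frozen=True)
class TranscriptTemplate:
    """A known transcript used as a template by the simulator."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom


@dataclass
class FilterReport:
    """Per-stage removal accounting for the filter cascade."""

    n_input: int = 0
    n_removed_uspp: int = 0
    n_removed_negative: int = 0
    samples_without_negative: list[str] = field(default_factory=list)

    @property
    def n_surviving(self) -> int:
        return self.n_input - self.n_removed_uspp - self.n_removed_negative

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"stage": "input", "n": self.n_input},
                {"stage": "after_uspp", "n": self.n_input - self.n_removed_uspp},
                {"stage": "after_negative_control", "n": self.n_surviving},
            ]
        )


def flag_unspecific_probes(probes: pd.DataFrame, genome: dict[str, str]) -> pd.DataFrame:
    """Count exact genomic matches of each probe on both strands.

    ``probes`` needs probe_id/chrom/start/end columns; sequences are taken
    from a ``seq`` column when present, else from the genome.  Returns a
    copy with ``n_matches`` and ``unspecific`` (n_matches != 1) columns;
    probes absent from the genome get count 0 and a warning, since that
    indicates a probe-layout/genome mismatch.
    """
    lengths = set(int(e) - int(s) for s, e in zip(probes["start"], probes["end"]))
    counters: dict[int, Counter] = {}
    for k in lengths:
        c: Counter = Counter()
        for seq in genome.values():
            s = seq.upper()
            for i in range(len(s) - k + 1):
                c[s[i : i + k]] += 1
        counters[k] = c
    out = probes.copy()
    counts = []
    for _, row in out.iterrows():
        k = int(row["end"]) - int(row["start"])
        if "seq" in out.columns and isinstance(row.get("seq"), str):
            pseq = row["seq"].upper()
        else:
            pseq = genome[row["chrom"]][int(row["start"]) : int(row["end"])].upper()
        c = counters[k]
        rc = _revcomp(pseq)
        n = c.get(pseq, 0) + (c.get(rc, 0) if rc != pseq else 0)
        counts.append(n)
    out["n_matches"] = counts
    out["unspecific"] = out["n_matches"] != 1
    n_absent = int((out["n_matches"] == 0).sum())
    if n_absent:
        warnings.warn(
            f"{n_absent} probe(s) have no exact genomic match; probe layout and genome may disagree",
            stacklevel=2,
        )
    return out


def _transcript_seq(tx: TranscriptTemplate, genome: dict[str, str]) -> tuple[str, list[int]]:
    """Spliced transcript sequence in genomic + orientation, with a map
    from transcript position to genomic position."""
    seq_parts, posmap = [], []
    chrom_seq = genome[tx.chrom]
    for ex in sorted(tx.exons, key=lambda e: e.start):
        seq_parts.append(chrom_seq[ex.start : ex.end].upper())
        posmap.extend(range(ex.start, ex.end))
    return "".join(seq_parts), posmap


def _positions_to_intervals(chrom: str, positions: list[int]) -> list[GenomicInterval]:
    out = []
    run_start = prev = None
    for p in positions:
        if prev is None or p != prev + 1:
            if run_start is not None:
                out.append(GenomicInterval(chrom, run_start, prev + 1))
            run_start = p
        prev = p
    if run_start is not None:
        out.append(GenomicInterval(chrom, run_start, prev + 1))
    return out


def _hamming_le(a: str, b: str, limit: int) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return False
    return True


def simulate_racearray(
    transcripts: list[TranscriptTemplate],
    primers,
    probes: pd.DataFrame,
    genome: dict[str, str],
    params: SimulatorParams = SimulatorParams(),
    gene_exons: dict[str, list[GenomicInterval]] | None = None,
) -> pd.DataFrame:
    """In-silico RACE followed by in-silico hybridization.

    A primer primes a transcript wherever the transcript's exonic sequence
    matches the primer's 3' seed within ``max_mismatches``; the simulated
    product runs from the priming site to the transcript end in the
    primer's amplification direction.  Every probe sharing at least
    ``hyb_min_match`` contiguous bases with a product (either strand)
    becomes a simulated positive probe (SPP), classed ``bona_fide`` when it
    overlaps an exon of the primer's own locus and ``USPP`` otherwise.

    ``gene_exons`` maps gene_id to its exon union; when omitted it is
    derived from the transcript templates.  Returns a DataFrame with one
    row per (probe, source primer) SPP: probe_id, chrom, start, end,
    primer_id, gene_id, klass.
    """
    if gene_exons is None:
        gene_exons = defaultdict(list)
        for tx in transcripts:
            gene_exons[tx.gene_id].extend(tx.exons)
        gene_exons = {g: meld_intervals(ivs) for g, ivs in gene_exons.items()}

    khyb = params.hyb_min_match
    probe_kmers: list[tuple] = []
    for _, row in probes.iterrows():
        pseq = (
            row["seq"].upper()
            if "seq" in probes.columns and isinstance(row.get("seq"), str)
            else genome[row["chrom"]][int(row["start"]) : int(row["end"])].upper()
        )
        kmers = {pseq[i : i + khyb] for i in range(max(1, len(pseq) - khyb + 1))}
        kmers |= {_revcomp(k) for k in kmers}
        probe_kmers.append((row, kmers))

    tx_cache = {tx.transcript_id: _transcript_seq(tx, genome) for tx in transcripts}
    rows = []
    for primer in primers:
        span = primer.span
        chrom_seq = genome[span.chrom]
        slen = min(params.seed_len, len(span))
        if primer.amp_direction == "+":
            seed = chrom_seq[span.end - slen : span.end].upper()
        else:
            seed = chrom_seq[span.start : span.start + slen].upper()
        product_kmers: set[str] = set()
        for tx in transcripts:
            seq, posmap = tx_cache[tx.transcript_id]
            if tx.chrom != span.chrom:
                continue
            for i in range(len(seq) - slen + 1):
                if not _hamming_le(seq[i : i + slen], seed, params.max_mismatches):
                    continue
                if primer.amp_direction == "+":
                    product = seq[i:]
                else:
                    product = seq[: i + slen]
                for j in range(len(product) - khyb + 1):
                    product_kmers.add(product[j : j + khyb])
        if not product_kmers:
            continue
        target_exons = gene_exons.get(primer.gene_id, [])
        for row, kmers in probe_kmers:
            if kmers & product_kmers:
                probe_iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
                bona = any(probe_iv.overlaps(ex) for ex in target_exons)
                rows.append(
                    {
                        "probe_id": row["probe_id"],
                        "chrom": row["chrom"],
                        "start": int(row["start"]),
                        "end": int(row["end"]),
                        "primer_id": primer.primer_id,
                        "gene_id": primer.gene_id,
                        "klass": "bona_fide" if bona else "USPP",
                    }
                )
    return pd.DataFrame(
        rows, columns=["probe_id", "chrom", "start", "end", "primer_id", "gene_id", "klass"]
    )


def apply_uspp_filter(
    frags,
    spps: pd.DataFrame,
    pool_members: dict[str, set[str]],
    report: FilterReport | None = None,
):
    """Remove fragments overlapping a USPP originating from a primer of
    their own pool.  Bona fide SPPs never cause a removal."""
    if report is None:
        report = FilterReport(n_input=len(frags))
    uspp = spps.loc[spps["klass"] == "USPP"] if len(spps) else spps
    by_chrom: dict[str, list] = defaultdict(list)
    if len(uspp):
        for _, row in uspp.iterrows():
            by_chrom[row["chrom"]].append(
                (GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])), row["primer_id"])
            )
    survivors = []
    for f in frags:
        pool = pool_members.get(f.experiment.pool_id, set())
        hit = any(
            iv.overlaps(f.interval) and primer_id in pool
            for iv, primer_id in by_chrom.get(f.interval.chrom, [])
        )
        if hit:
            report.n_removed_uspp += 1
        else:
            survivors.append(f)
    return survivors, report


def apply_negative_control_filter(frags, negative_frags, report: FilterReport | None = None):
    """Remove fragments overlapping a negative-control fragment called in
    the same sample.  Samples with no negative track pass through with a
    warning."""
    if report is None:
        report = FilterReport(n_input=len(frags))
    neg_by_sample: dict[str, list[GenomicInterval]] = defaultdict(list)
    for nf in negative_frags:
        neg_by_sample[nf.experiment.sample_id].append(nf.interval)
    missing = set()
    survivors = []
    for f in frags:
        sample = f.experiment.sample_id
        if sample not in neg_by_sample:
            missing.add(sample)
            survivors.append(f)
            continue
        if any(iv.overlaps(f.interval) for iv in neg_by_sample[sample]):
            report.n_removed_negative += 1
        else:
            survivors.append(f)
    if missing:
        report.samples_without_negative = sorted(missing)
        warnings.warn(
            f"no negative-control track for sample(s) {sorted(missing)}; passed through unfiltered",
            stacklevel=2,
        )
    return survivors, report
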