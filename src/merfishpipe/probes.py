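"""Encoding-probe design: target regions, filters, and probe assembly.

Each gene is targeted by up to 92 encoding probes. A probe's 30-nt target
region must satisfy sequence-composition filters (GC fraction 0.30-0.70,
nearest-neighbor melting temperature 60-80 C), specificity filters (the
fraction of the window's 17-mers unique to the target gene / isoform must be
at least 0.75), and must share no 16-mer with an rRNA/tRNA blacklist
("no homology longer than 15 nt"). Passing windows are tiled greedily left
to right without overlap; if more than ``max_probes`` remain, a seeded
random subset of ``max_probes`` is kept.

The assembled probe concatenates a 20-nt forward primer, three 20-nt
readout sequences drawn from the four readouts of the gene's barcode
(a random 3-of-4 choice per probe), the 30-nt target region, and a 20-nt
promoter/reverse-primer sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import MeltingTemp, gc_fraction

__all__ = [
    "ProbeRecord",
    "ProbeSet",
    "TargetRegionParams",
    "KmerSpecificityIndex",
    "melting_temperature",
    "design_target_regions",
    "assemble_probes",
    "write_probes_fasta",
]

WINDOW = 30  # nt, target-region length
BLACKLIST_K = 16  # shared 16-mer = homology longer than 15 nt
SPECIFICITY_K = 17


def melting_temperature(seq: str, na_mm: float = 300.0, formamide_pct: float = 0.0) -> float:
    """Nearest-neighbor Tm in Celsius at the given monovalent salt.

    ``formamide_pct`` applies the linear -0.6 C per percent correction; the
    default of 0 matches the convention under which the 60-80 C filter band
    is expressed.
    """
    tm = MeltingTemp.Tm_NN(Seq(seq), Na=na_mm, dnac1=5, dnac2=0)
    return float(tm) - 0.6 * formamide_pct


@dataclass
class TargetRegionParams:
    """Filter bounds for candidate 30-nt target regions."""

    gc_min: float = 0.30
    gc_max: float = 0.70
    tm_min: float = 60.0
    tm_max: float = 80.0
    spec_min: float = 0.75
    isoform_spec_min: float = 0.75
    max_probes: int = 92
    na_mm: float = 300.0
    formamide_pct: float = 0.0


class KmerSpecificityIndex:
    """17-mer occurrence index over a transcriptome for specificity scoring.

    ``sequences`` maps isoform id -> sequence; ``isoform_to_gene`` maps
    isoform id -> gene id (identity if omitted). The gene specificity of a
    window is the fraction of its 17-mers that occur in no other gene;
    isoform specificity likewise at the isoform level.
    """

    def __init__(
        self,
        sequences: dict[str, str],
        isoform_to_gene: dict[str, str] | None = None,
    ) -> None:
        self.isoform_to_gene = isoform_to_gene or {name: name for name in sequences}
        self._kmer_genes: dict[str, set[str]] = {}
        self._kmer_isoforms: dict[str, set[str]] = {}
        for iso, seq in sequences.items():
            gene = self.isoform_to_gene[iso]
            seq = seq.upper()
            for i in range(len(seq) - SPECIFICITY_K + 1):
                kmer = seq[i : i + SPECIFICITY_K]
                self._kmer_genes.setdefault(kmer, set()).add(gene)
                self._kmer_isoforms.setdefault(kmer, set()).add(iso)

    def specificity(self, window: str, isoform: str) -> tuple[float, float]:
        """(isoform_specificity, gene_specificity) of a window."""
        gene = self.isoform_to_gene.get(isoform, isoform)
        kmers = [
            window[i : i + SPECIFICITY_K]
            for i in range(len(window) - SPECIFICITY_K + 1)
        ]
        if not kmers:
            return 1.0, 1.0
        iso_unique = sum(
            1 for k in kmers if self._kmer_isoforms.get(k, {isoform}) <= {isoform}
        )
        gene_unique = sum(
            1 for k in kmers if self._kmer_genes.get(k, {gene}) <= {gene}
        )
        return iso_unique / len(kmers), gene_unique / len(kmers)


@dataclass
class ProbeRecord:
    gene: str
    target_start: int  # 0-based transcript offset
    target_seq: str
    gc_fraction: float
    tm_celsius: float
    isoform_specificity: float = 1.0
    gene_specificity: float = 1.0
    readout_ids: tuple[int, int, int] | None = None
    assembled_seq: str | None = None

    def __post_init__(self) -> None:
        if len(self.target_seq) != WINDOW:
            raise ValueError("target region must be 30 nt")


@dataclass
class ProbeSet:
    """All assembled encoding probes for a panel."""

    probes: list[ProbeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.probes)

    def for_gene(self, gene: str) -> list[ProbeRecord]:
        return [p for p in self.probes if p.gene == gene]


def _blacklist_kmers(blacklist_seqs) -> set[str]:
    kmers: set[str] = set()
    for seq in blacklist_seqs:
        seq = str(seq).upper()
        for i in range(len(seq) - BLACKLIST_K + 1):
            kmers.add(seq[i : i + BLACKLIST_K])
    return kmers


def design_target_regions(
    transcript: str,
    gene: str,
    params: TargetRegionParams | None = None,
    specificity_index: KmerSpecificityIndex | None = None,
    blacklist_seqs=(),
    seed: int = 0,
) -> list[ProbeRecord]:
    """Select non-overlapping 30-nt target regions passing all filters.

    Every 30-nt window of the transcript is scored; windows failing any
    bound are discarded; survivors are tiled greedily left to right without
    overlap; a seeded random downsample caps the result at
    ``params.max_probes``, re-sorted by position. Without a specificity
    index both specificity scores are 1.
    """
    params = params or TargetRegionParams()
    transcript = transcript.upper()
    if len(transcript) < WINDOW:
        warnings.warn(f"transcript for {gene!r} shorter than {WINDOW} nt; no probes")
        return []
    bad_kmers = _blacklist_kmers(blacklist_seqs)

    passing: list[ProbeRecord] = []
    for start in range(len(transcript) - WINDOW + 1):
        window = transcript[start : start + WINDOW]
        gc = gc_fraction(window)
        if not params.gc_min <= gc <= params.gc_max:
            continue
        tm = melting_temperature(window, params.na_mm, params.formamide_pct)
        if not params.tm_min <= tm <= params.tm_max:
            continue
        if specificity_index is not None:
            iso_spec, gene_spec = specificity_index.specificity(window, gene)
        else:
            iso_spec = gene_spec = 1.0
        if iso_spec < params.isoform_spec_min or gene_spec < params.spec_min:
            continue
        if bad_kmers and any(
            window[i : i + BLACKLIST_K] in bad_kmers
            for i in range(WINDOW - BLACKLIST_K + 1)
        ):
            continue
        passing.append(
            ProbeRecord(
                gene=gene,
                target_start=start,
                target_seq=window,
                gc_fraction=float(gc),
                tm_celsius=tm,
                isoform_specificity=iso_spec,
                gene_specificity=gene_spec,
            )
        )

    tiled: list[ProbeRecord] = []
    next_free = 0
    for rec in passing:  # already in left-to-right order
        if rec.target_start >= next_free:
            tiled.append(rec)
            next_free = rec.target_start + WINDOW
    if len(tiled) > params.max_probes:
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(len(tiled), size=params.max_probes, replace=False))
        tiled = [tiled[i] for i in keep]
    return tiled


def assemble_probes(
    records: list[ProbeRecord],
    barcode_on_bits: dict[str, tuple[int, ...]],
    readout_sequences: list[str],
    primer_5p: str,
    promoter_3p: str,
    seed: int = 0,
) -> ProbeSet:
    """Attach readout sequences and flanking primers to target regions.

    ``barcode_on_bits[gene]`` gives the four on-bit indices of the gene's
    barcode; each index selects one 20-nt readout from
    ``readout_sequences``. Each probe carries 3 of the gene's 4 readouts;
    the omitted readout follows a seeded shuffle of a balanced exclusion
    list, so across a gene's probes each readout appears in three quarters
    of them (up to rounding).
    """
    rng = np.random.default_rng(seed)
    # balanced exclusion schedule per gene: each readout sits out n/4 probes
    by_gene: dict[str, list[ProbeRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, []).append(rec)
    out = ProbeSet()
    for gene, recs in by_gene.items():
        bits = barcode_on_bits[gene]
        if len(bits) != 4:
            raise ValueError(f"gene {gene!r} barcode must have exactly 4 on-bits")
        for b in bits:
            if b >= len(readout_sequences):
                raise KeyError(f"readout index {b} has no sequence")
        schedule = [bits[i % 4] for i in range(len(recs))]
        rng.shuffle(schedule)
        for rec, omit in zip(recs, schedule):
            chosen = tuple(sorted(int(b) for b in bits if b != omit))
            readouts = [readout_sequences[i] for i in chosen]
            assembled = (
                primer_5p
                + readouts[0]
                + rec.target_seq
                + readouts[1]
                + readouts[2]
                + promoter_3p
            )
            out.probes.append(
                ProbeRecord(
                    gene=rec.gene,
                    target_start=rec.target_start,
                    target_seq=rec.target_seq,
                    gc_fraction=rec.gc_fraction,
                    tm_celsius=rec.tm_celsius,
                    isoform_specificity=rec.isoform_specificity,
                    gene_specificity=rec.gene_specificity,
                    readout_ids=chosen,
                    assembled_seq=assembled,
                )
            )
    return out


def write_probes_fasta(probe_set: ProbeSet, path: str | Path) -> None:
    """Write assembled probes as FASTA, headers ``gene|index|start|readouts``."""
    records = []
    for i, p in enumerate(probe_set.probes):
        rid = ",".join(map(str, p.readout_ids or ()))
        records.append(
            SeqRecord(
                Seq(p.assembled_seq or p.target_seq),
                id=f"{p.gene}|{i}|{p.target_start}|{rid}",
                description="",
            )
        )
    SeqIO.write(records, str(path), "fasta")


def read_fasta_dict(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
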