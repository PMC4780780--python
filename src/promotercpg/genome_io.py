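"""Genome and annotation input: gene models, TSS resolution, promoter windows.

Coordinates are 0-based, half-open everywhere inside the package; GFF3's
1-based inclusive coordinates are converted at the parsing boundary. The TSS
of a plus-strand gene is the feature start, of a minus-strand gene the
feature end, both expressed as the 0-based coordinate of the first
transcribed base.

Promoter windows are reported 5'->3' in the gene's transcriptional
orientation: minus-strand slices are reverse-complemented so that relative
position p in [-upstream, +downstream) maps to string index
``offset_of_tss + p``.
"""

from __future__ import annotations

import io
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from . import _seq

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "PromoterWindow",
    "CodonUsageTable",
    "load_genome",
    "parse_gene_models",
    "extract_promoter_window",
    "filter_full_upstream",
    "compute_codon_usage",
    "write_windows_fasta",
    "read_windows_fasta",
]


@dataclass
class GeneModel:
    """One annotated gene: location of its TSS plus functional labels."""

    gene_id: str
    scaffold: str
    strand: str
    tss: int
    kegg_classes: set = field(default_factory=set)
    in_focal_set: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: negative TSS coordinate")


@dataclass
class PromoterWindow:
    """A TSS-anchored sequence window in transcriptional orientation.

    ``seq[offset_of_tss]`` is the TSS base (relative position 0); relative
    position p maps to index ``offset_of_tss + p`` where present.
    """

    gene_id: str
    seq: str
    offset_of_tss: int
    has_full_upstream: bool
    strand: str = "+"
    has_full_downstream: bool = True

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def rel_start(self) -> int:
        """Smallest relative position present in the window."""
        return -self.offset_of_tss

    @property
    def rel_end(self) -> int:
        """One past the largest relative position present."""
        return len(self.seq) - self.offset_of_tss


@dataclass
class CodonUsageTable:
    """Fraction of each of the 64 codons among all counted codons."""

    freq: dict

    def __post_init__(self):
        total = sum(self.freq.values())
        if any(v < 0 for v in self.freq.values()):
            raise ValueError("codon fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"codon fractions must sum to 1, got {total!r}")


ALL_CODONS = tuple(a + b + c for a in _seq.BASES for b in _seq.BASES for c in _seq.BASES)


def load_genome(path) -> dict:
    """Load a (multi-)FASTA into a dict scaffold -> upper-case sequence string."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True, rebuild=True)
    genome = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return genome


def _open_lines(source) -> Iterator[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        yield from source
    else:
        yield from source


def _parse_gff_attributes(attr_field: str) -> dict:
    out = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gene_models(source, feature_type: str = "gene", id_attr: str = "ID") -> list:
    """Parse GFF3-like annotation into GeneModels.

    ``source`` may be a path, an open text handle, or an iterable of lines.
    Only rows whose feature type matches ``feature_type`` are considered.
    Rows with an unusable strand, coordinates or missing identifier are
    skipped with a logged warning; a duplicated gene identifier is a hard
    error because every downstream table is keyed by it.
    """
    genes: list = []
    seen: set = set()
    for lineno, line in enumerate(_open_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            continue
        scaffold, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
        if ftype != feature_type:
            continue
        try:
            start_1b, end_1b = int(start_s), int(end_s)
        except ValueError:
            logger.warning("line %d: non-integer coordinates, gene skipped", lineno)
            continue
        if strand not in ("+", "-"):
            logger.warning("line %d: missing/unknown strand %r, gene skipped", lineno, strand)
            continue
        gene_id = _parse_gff_attributes(attrs).get(id_attr)
        if not gene_id:
            logger.warning("line %d: no %s attribute, gene skipped", lineno, id_attr)
            continue
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in annotation")
        seen.add(gene_id)
        # 1-based inclusive -> 0-based coordinate of the first transcribed base
        tss = start_1b - 1 if strand == "+" else end_1b - 1
        genes.append(GeneModel(gene_id=gene_id, scaffold=scaffold, strand=strand, tss=tss))
    return genes


def extract_promoter_window(
    genome: Mapping[str, str],
    gene: GeneModel,
    upstream: int = 3000,
    downstream: int = 500,
) -> PromoterWindow:
    """Extract the [-upstream, +downstream) window around a gene's TSS.

    Plus-strand genes cover genomic ``[tss-upstream, tss+downstream)``;
    minus-strand genes cover ``(tss-downstream, tss+upstream]`` read
    descending and complemented. Truncation at either scaffold end is
    permitted: missing positions are simply absent from ``seq`` and
    ``has_full_upstream`` / ``has_full_downstream`` record which side was
    clipped.
    """
    if gene.scaffold not in genome:
        raise KeyError(f"gene {gene.gene_id}: scaffold {gene.scaffold!r} not in genome")
    scaf = genome[gene.scaffold]
    L = len(scaf)
    if not 0 <= gene.tss < L:
        raise ValueError(f"gene {gene.gene_id}: TSS {gene.tss} outside scaffold of length {L}")
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
        gstart, gend = max(0, start), min(L, end)
        seq = scaf[gstart:gend].upper()
        offset = gene.tss - gstart
        full_up, full_down = start >= 0, end <= L
    else:
        # genomic ascending slice, then reverse-complement to transcriptional orientation
        start, end = gene.tss - downstream + 1, gene.tss + upstream + 1
        gstart, gend = max(0, start), min(L, end)
        seq = _seq.revcomp(scaf[gstart:gend]).upper()
        offset = gend - 1 - gene.tss
        full_up, full_down = end <= L, start >= 0
    return PromoterWindow(
        gene_id=gene.gene_id,
        seq=seq,
        offset_of_tss=offset,
        has_full_upstream=full_up,
        strand=gene.strand,
        has_full_downstream=full_down,
    )


def filter_full_upstream(windows: Iterable[PromoterWindow]) -> list:
    """Keep only windows with the complete upstream domain, preserving order."""
    return [w for w in windows if w.has_full_upstream]


def compute_codon_usage(cds_sequences: Iterable[str]) -> CodonUsageTable:
    """Codon usage over a collection of coding sequences.

    Sequences whose length is not a multiple of 3 are skipped with a
    warning; codons containing any ambiguous base are excluded from both
    numerator and denominator.
    """
    counts: Counter = Counter()
    for i, cds in enumerate(cds_sequences):
        cds = cds.upper()
        if len(cds) % 3 != 0:
            logger.warning("CDS #%d length %d not divisible by 3, skipped", i, len(cds))
            continue
        for j in range(0, len(cds), 3):
            codon = cds[j : j + 3]
            if all(b in _seq.BASES for b in codon):
                counts[codon] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous codons found in input CDS set")
    freq = {codon: counts.get(codon, 0) / total for codon in ALL_CODONS}
    return CodonUsageTable(freq=freq)


def write_windows_fasta(windows: Iterable[PromoterWindow], path, width: int = 80) -> None:
    """Write windows as FASTA with `gene_id|strand|offset_of_tss|full_upstream` headers."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.gene_id}|{w.strand}|{w.offset_of_tss}|{int(w.has_full_upstream)}\n")
            for i in range(0, len(w.seq), width):
                fh.write(w.seq[i : i + width] + "\n")


def read_windows_fasta(path) -> list:
    """Read windows written by :func:`write_windows_fasta`."""
    windows = []
    name, chunks = None, []

    def _flush():
        if name is None:
            return
        gene_id, strand, offset, full = name.split("|")
        windows.append(
            PromoterWindow(
                gene_id=gene_id,
                seq="".join(chunks),
                offset_of_tss=int(offset),
                has_full_upstream=bool(int(full)),
                strand=strand,
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                _flush()
                name, chunks = line[1:], []
            elif line:
                chunks.append(line)
    _flush()
    return windows
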