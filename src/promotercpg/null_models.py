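"""Randomized control gene models and the mirror-image GpC control.

Controls emulate genome composition, not gene structure: each control gene
gets a 3-kb upstream domain of bases drawn i.i.d. from the genome-wide base
frequencies and a 500-bp "first exon" of codons drawn i.i.d. from a codon
usage table (167 codons, final base dropped since 500 is not divisible by
3). One shared control set is generated per configuration, reproducible
from its seed.

The mirror control counts the GpC dinucleotide, which has the same base
composition as CpG but is not a methylation substrate. Counting GpC on the
forward sequence is equivalent to counting CpG on the reversed sequence
(position-reversed), so the mirror profile is computed directly with the
reversed motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _seq
from .density_profiler import DensityProfile, ProfileConfig, mirror_config, profile_windows
from .genome_io import ALL_CODONS, CodonUsageTable, PromoterWindow

__all__ = [
    "NullModelConfig",
    "genome_base_frequencies",
    "generate_randomized_models",
    "mirror_control_profile",
]

_UNIFORM_CODONS = CodonUsageTable(freq={c: 1 / 64 for c in ALL_CODONS})


def _default_codon_usage() -> CodonUsageTable:
    return CodonUsageTable(freq=dict(_UNIFORM_CODONS.freq))


@dataclass
class NullModelConfig:
    """Configuration of the randomized control generator.

    Defaults follow the published control set: 20,000 models of a 3,000-bp
    upstream domain plus a 500-bp first exon. ``base_freqs`` accepts a
    mapping with keys A/C/G/T or a length-4 sequence in that order;
    uniform composition and codon usage are placeholders to be replaced by
    :func:`genome_base_frequencies` and a species codon table in real use.
    """

    n_models: int = 20_000
    upstream_len: int = 3000
    exon_len: int = 500
    base_freqs: object = (0.25, 0.25, 0.25, 0.25)
    codon_usage: CodonUsageTable = field(default_factory=_default_codon_usage)
    seed: int = 0

    def __post_init__(self):
        self.base_freqs = _seq.base_freq_array(self.base_freqs)
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")


def genome_base_frequencies(genome: Mapping[str, str]) -> np.ndarray:
    """Genome-wide A,C,G,T fractions; ambiguity codes excluded from the denominator."""
    counts = np.zeros(5, dtype=np.int64)
    for seq in genome.values():
        codes = _seq.encode(seq)
        counts += np.bincount(codes, minlength=5)
    total = counts[:4].sum()
    if total == 0:
        raise ValueError("genome contains no unambiguous bases")
    return counts[:4] / total


def generate_randomized_models(config: NullModelConfig) -> list:
    """Generate the randomized control gene models.

    Upstream bases are i.i.d. from ``base_freqs``; the exon is 167 i.i.d.
    codons truncated to ``exon_len`` bases. Byte-identical output for a
    given config and seed.
    """
    rng = np.random.default_rng(config.seed)
    n, up, ex = config.n_models, config.upstream_len, config.exon_len

    cum_bases = np.cumsum(config.base_freqs)
    upstream = np.searchsorted(cum_bases, rng.random((n, up)), side="right").astype(np.uint8)

    probs = np.array([config.codon_usage.freq.get(c, 0.0) for c in ALL_CODONS])
    if probs.sum() <= 0:
        raise ValueError("degenerate codon usage table: all fractions zero")
    probs = probs / probs.sum()
    n_codons = -(-ex // 3)  # 167 codons for a 500-bp exon
    codon_idx = np.searchsorted(np.cumsum(probs), rng.random((n, n_codons)), side="right")
    codon_codes = np.array([_seq.encode(c) for c in ALL_CODONS], dtype=np.uint8)
    exon = codon_codes[codon_idx].reshape(n, n_codons * 3)[:, :ex]

    seqs = np.concatenate([upstream, exon], axis=1)
    width = len(str(n - 1))
    return [
        PromoterWindow(
            gene_id=f"null_{i:0{width}d}",
            seq=_seq.decode(seqs[i]),
            offset_of_tss=up,
            has_full_upstream=True,
        )
        for i in range(n)
    ]


def mirror_control_profile(
    windows: Sequence[PromoterWindow],
    config: ProfileConfig = ProfileConfig(),
) -> DensityProfile:
    """Aggregate profile of the mirror-image motif (GpC for a CpG analysis)."""
    if not windows:
        raise ValueError("mirror control requires at least one window")
    return profile_windows(windows, mirror_config(config))
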