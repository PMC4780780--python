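"""Synthetic genomes with a known, position-dependent CpG structure.

The generator produces a complete, self-consistent input set — multi-
scaffold genome FASTA, GFF3 gene annotation, KEGG class map and focal gene
list — in which every promoter's CpG content follows a known generative
profile, so the whole pipeline can be exercised end to end and parameter
recovery can be checked against stored truth.

Generative model
----------------
Each gene's 3,500-bp window (3,000 bp upstream + 500 bp of first exon) is
emitted left to right by a first-order process with a target CpG
observed/expected profile rho(x):

* background level ``rho_background`` up to ``ramp_start`` (default -2000),
* linear rise to ``rho_background * ramp_peak_factor`` at the TSS,
* constant at the peak over the exon [0, +500),
* multiplied by any class-specific or focal-set offset over its interval.

The emission keeps P(C) = f_C at every position and sets
P(G | previous base C at x) = rho(x) * f_G, rebalancing P(G | previous not
C) so that the marginal G frequency stays exactly f_G; A and T share the
residual mass in proportion to their frequencies. Consequently the CpG
start probability at x is exactly f_C * rho(x) * f_G while the
mononucleotide composition is position-independent — the windowed
observed/expected statistic of the profiling pipeline estimates rho(x)
directly, without composition confounds.

Minus-strand genes are embedded in the genome as reverse complements, so
strand-aware extraction must recover the emitted window exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from . import _seq
from .functional_groups import DEFAULT_KEGG_CLASSES
from .genome_io import GeneModel, PromoterWindow

__all__ = [
    "SyntheticGenomeConfig",
    "SyntheticDataset",
    "rho_profile",
    "simulate_promoter",
    "simulate_windows",
    "simulate_dataset",
]


@dataclass
class SyntheticGenomeConfig:
    """Generative parameters of the synthetic genome.

    ``class_rho_offsets`` maps a class label to ``(factor, start, end)``:
    rho is multiplied by ``factor`` over relative positions [start, end)
    for genes of that class. ``focal_rho_offset`` does the same for genes
    flagged focal. Offsets default to none (the null condition).
    """

    n_genes: int = 5000
    scaffold_len: int = 500_000
    intergenic_gap: int = 1000
    base_freqs: object = (0.25, 0.25, 0.25, 0.25)
    rho_background: float = 0.6
    ramp_start: int = -2000
    ramp_peak_factor: float = 1.38
    upstream_len: int = 3000
    downstream_len: int = 500
    class_vocabulary: tuple = DEFAULT_KEGG_CLASSES
    class_rho_offsets: Mapping[str, tuple] = field(default_factory=dict)
    multiclass_fraction: float = 0.1
    focal_fraction: float = 0.01
    focal_rho_offset: tuple = None
    minus_strand_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.base_freqs = _seq.base_freq_array(self.base_freqs)
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.rho_background < 0:
            raise ValueError("rho_background must be >= 0")
        if not -self.upstream_len <= self.ramp_start <= 0:
            raise ValueError("ramp_start must lie in the upstream domain")
        for frac in (self.multiclass_fraction, self.focal_fraction, self.minus_strand_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def window_len(self) -> int:
        return self.upstream_len + self.downstream_len


@dataclass
class SyntheticDataset:
    """In-memory synthetic inputs plus generative truth."""

    config: SyntheticGenomeConfig
    genes: list
    windows: list
    genome: dict
    kegg_map: dict
    focal_set: set
    truth: dict


def rho_profile(
    config: SyntheticGenomeConfig,
    position: int,
    classes: Sequence[str] = (),
    focal: bool = False,
) -> float:
    """Target CpG observed/expected at one relative position."""
    x = position
    if not -config.upstream_len <= x < config.downstream_len:
        raise ValueError(f"position {x} outside the window")
    if x <= config.ramp_start:
        rho = config.rho_background
    elif x < 0:
        frac = (x - config.ramp_start) / (0 - config.ramp_start)
        rho = config.rho_background * (1.0 + (config.ramp_peak_factor - 1.0) * frac)
    else:
        rho = config.rho_background * config.ramp_peak_factor
    for cls in classes:
        off = config.class_rho_offsets.get(cls)
        if off is not None and off[1] <= x < off[2]:
            rho *= off[0]
    if focal and config.focal_rho_offset is not None:
        f, lo, hi = config.focal_rho_offset
        if lo <= x < hi:
            rho *= f
    return rho


def _rho_array(config: SyntheticGenomeConfig, classes: Sequence[str], focal: bool) -> np.ndarray:
    xs = np.arange(-config.upstream_len, config.downstream_len)
    return np.array([rho_profile(config, int(x), classes, focal) for x in xs])


def _emission_cum_tables(config: SyntheticGenomeConfig, classes: Sequence[str], focal: bool):
    """Cumulative next-base tables per position for prev-C and prev-not-C.

    Row i gives the distribution of the base emitted at window index i;
    the rho that applies is the one at the preceding (potential C)
    position, i - 1.
    """
    fA, fC, fG, fT = config.base_freqs
    if fC >= 1.0 or fA + fT <= 0:
        raise ValueError("base composition leaves no mass for the compensated emission")
    rho = _rho_array(config, classes, focal)
    rho_prev = np.concatenate([[rho[0]], rho[:-1]])

    pG_C = rho_prev * fG
    remC = 1.0 - fC - pG_C
    g = fG * (1.0 - rho_prev * fC) / (1.0 - fC)
    remN = 1.0 - fC - g
    at = fA + fT
    probsC = np.stack([remC * fA / at, np.full_like(rho, fC), pG_C, remC * fT / at], axis=1)
    probsN = np.stack([remN * fA / at, np.full_like(rho, fC), g, remN * fT / at], axis=1)
    for name, probs in (("prev-C", probsC), ("prev-non-C", probsN)):
        if (probs < -1e-12).any() or not np.isfinite(probs).all():
            raise ValueError(
                f"rho profile not generable with these base frequencies ({name} branch): "
                "rho*f_G or rho*f_C too large"
            )
    cumC = np.cumsum(np.maximum(probsC, 0.0), axis=1)
    cumN = np.cumsum(np.maximum(probsN, 0.0), axis=1)
    cumC[:, 3] = 1.0
    cumN[:, 3] = 1.0
    return cumC, cumN


def _simulate_group(
    config: SyntheticGenomeConfig,
    classes: Sequence[str],
    focal: bool,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Emit n windows (rows of base codes) that share one rho profile."""
    L = config.window_len
    cumC, cumN = _emission_cum_tables(config, classes, focal)
    cum_base = np.cumsum(config.base_freqs)
    cum_base[3] = 1.0
    seqs = np.empty((n, L), dtype=np.uint8)
    prev = np.minimum(np.searchsorted(cum_base, rng.random(n), side="right"), 3).astype(np.uint8)
    seqs[:, 0] = prev
    for i in range(1, L):
        u = rng.random(n)
        nxt_c = np.searchsorted(cumC[i], u, side="right")
        nxt_n = np.searchsorted(cumN[i], u, side="right")
        prev = np.minimum(np.where(prev == _seq.C, nxt_c, nxt_n), 3).astype(np.uint8)
        seqs[:, i] = prev
    return seqs


def simulate_promoter(
    config: SyntheticGenomeConfig,
    gene_attrs: Mapping = None,
    rng: np.random.Generator = None,
) -> str:
    """One 3,500-bp window in transcriptional orientation."""
    gene_attrs = gene_attrs or {}
    if rng is None:
        rng = np.random.default_rng(config.seed)
    codes = _simulate_group(
        config,
        tuple(gene_attrs.get("classes", ())),
        bool(gene_attrs.get("focal", False)),
        1,
        rng,
    )
    return _seq.decode(codes[0])


def _draw_gene_attrs(config: SyntheticGenomeConfig, rng: np.random.Generator):
    n = config.n_genes
    vocab = list(config.class_vocabulary)
    strands = np.where(rng.random(n) < config.minus_strand_fraction, "-", "+")
    primary = rng.integers(0, len(vocab), size=n)
    extra = rng.random(n) < config.multiclass_fraction
    second = (primary + 1 + rng.integers(0, len(vocab) - 1, size=n)) % len(vocab)
    focal = rng.random(n) < config.focal_fraction
    classes = []
    for i in range(n):
        cs = {vocab[primary[i]]}
        if extra[i]:
            cs.add(vocab[second[i]])
        classes.append(cs)
    return strands, classes, focal


def _simulate_all_windows(config, classes, focal, rng) -> np.ndarray:
    """Windows for all genes, grouped by shared rho profile for speed."""
    n = config.n_genes
    keys = [(tuple(sorted(classes[i])), bool(focal[i])) for i in range(n)]
    out = np.empty((n, config.window_len), dtype=np.uint8)
    for key in sorted(set(keys)):
        idx = [i for i, k in enumerate(keys) if k == key]
        out[idx] = _simulate_group(config, key[0], key[1], len(idx), rng)
    return out


def simulate_windows(config: SyntheticGenomeConfig, attrs=None):
    """Generate promoter windows directly, without genome assembly.

    ``attrs``, if given, is a list of ``(classes, focal)`` per gene
    overriding the random label draw (used for balanced designs). Returns
    ``(windows, genes)`` with per-gene labels attached to the GeneModels;
    gene TSS coordinates are placeholders since no genome is built.
    """
    rng = np.random.default_rng(config.seed)
    if attrs is None:
        strands, classes, focal = _draw_gene_attrs(config, rng)
    else:
        strands = np.full(config.n_genes, "+")
        classes = [set(c) for c, _ in attrs]
        focal = np.array([bool(f) for _, f in attrs])
    seqs = _simulate_all_windows(config, classes, focal, rng)
    width = len(str(config.n_genes - 1))
    windows, genes = [], []
    for i in range(config.n_genes):
        gid = f"g{i:0{width}d}"
        windows.append(
            PromoterWindow(
                gene_id=gid,
                seq=_seq.decode(seqs[i]),
                offset_of_tss=config.upstream_len,
                has_full_upstream=True,
                strand=str(strands[i]),
            )
        )
        genes.append(
            GeneModel(
                gene_id=gid,
                scaffold="none",
                strand=str(strands[i]),
                tss=0,
                kegg_classes=set(classes[i]),
                in_focal_set=bool(focal[i]),
            )
        )
    return windows, genes


def simulate_dataset(config: SyntheticGenomeConfig, outdir=None) -> SyntheticDataset:
    """Generate the full input set: genome, annotation, labels and truth.

    Genes are laid out scaffold by scaffold as
    ``[spacer][window][spacer][window]...[spacer]`` with i.i.d. spacer
    bases; minus-strand windows are embedded reverse-complemented. If
    ``outdir`` is given, standard-format files (genome.fa, genes.gff3,
    kegg_map.tsv, focal_set.txt, truth.json) are written there;
    byte-identical for a given config.
    """
    L = config.window_len
    block = config.intergenic_gap + L
    per_scaffold = config.scaffold_len // block
    if per_scaffold < 1:
        raise ValueError(
            f"scaffold_len {config.scaffold_len} too short for one gene block of {block} bp"
        )

    rng = np.random.default_rng(config.seed)
    strands, classes, focal = _draw_gene_attrs(config, rng)
    seqs = _simulate_all_windows(config, classes, focal, rng)

    cum_base = np.cumsum(config.base_freqs)
    cum_base[3] = 1.0
    width = len(str(config.n_genes - 1))
    genome: dict = {}
    genes: list = []
    windows: list = []
    i = 0
    scaf_no = 0
    while i < config.n_genes:
        scaf_no += 1
        n_here = min(per_scaffold, config.n_genes - i)
        scaf_len = n_here * block + config.intergenic_gap
        spacer = np.minimum(
            np.searchsorted(cum_base, rng.random(scaf_len), side="right"), 3
        ).astype(np.uint8)
        scaf = spacer  # gene windows overwrite their slots below
        name = f"scaffold_{scaf_no}"
        for j in range(n_here):
            gid = f"g{i:0{width}d}"
            win = seqs[i]
            start = j * block + config.intergenic_gap
            if strands[i] == "+":
                scaf[start : start + L] = win
                tss = start + config.upstream_len
            else:
                scaf[start : start + L] = _seq.revcomp_codes(win)
                tss = start + config.downstream_len - 1
            genes.append(
                GeneModel(
                    gene_id=gid,
                    scaffold=name,
                    strand=str(strands[i]),
                    tss=tss,
                    kegg_classes=set(classes[i]),
                    in_focal_set=bool(focal[i]),
                )
            )
            windows.append(
                PromoterWindow(
                    gene_id=gid,
                    seq=_seq.decode(win),
                    offset_of_tss=config.upstream_len,
                    has_full_upstream=True,
                    strand=str(strands[i]),
                )
            )
            i += 1
        genome[name] = _seq.decode(scaf)

    kegg_map = {g.gene_id: set(g.kegg_classes) for g in genes}
    focal_set = {g.gene_id for g in genes if g.in_focal_set}
    cfg_dict = asdict(config)
    cfg_dict["base_freqs"] = [float(v) for v in config.base_freqs]
    cfg_dict["class_rho_offsets"] = {k: list(v) for k, v in config.class_rho_offsets.items()}
    truth = {
        "config": cfg_dict,
        "genes": [
            {
                "gene_id": g.gene_id,
                "scaffold": g.scaffold,
                "strand": g.strand,
                "tss": g.tss,
                "classes": sorted(g.kegg_classes),
                "focal": g.in_focal_set,
            }
            for g in genes
        ],
    }
    ds = SyntheticDataset(
        config=config,
        genes=genes,
        windows=windows,
        genome=genome,
        kegg_map=kegg_map,
        focal_set=focal_set,
        truth=truth,
    )
    if outdir is not None:
        _write_dataset(ds, outdir)
    return ds


def _write_dataset(ds: SyntheticDataset, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    join = lambda p: os.path.join(str(outdir), p)
    with open(join("genome.fa"), "w") as fh:
        for name, seq in ds.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(join("genes.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ds.genes:
            if g.strand == "+":
                start, end = g.tss + 1, g.tss + ds.config.downstream_len
            else:
                start, end = g.tss - ds.config.downstream_len + 2, g.tss + 1
            fh.write(
                f"{g.scaffold}\tpromotercpg_sim\tgene\t{start}\t{end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
    with open(join("kegg_map.tsv"), "w") as fh:
        for g in ds.genes:
            for cls in sorted(g.kegg_classes):
                fh.write(f"{g.gene_id}\t{cls}\n")
    with open(join("focal_set.txt"), "w") as fh:
        for gid in sorted(ds.focal_set):
            fh.write(gid + "\n")
    with open(join("truth.json"), "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
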