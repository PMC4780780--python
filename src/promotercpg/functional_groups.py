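"""KEGG class labels and focal gene sets.

Annotation here is purely declarative: a two-column TSV maps genes to
top-level KEGG classes and a plain id list names a focal gene set (for
example temperature-acclimation homologs). Building those inputs (BLAST
alignment, KO-to-class rollup) is upstream of this package.

For the group comparisons only genes carrying exactly one class are used,
so a gene annotated with several classes contributes to none of the
per-class gene sets.
"""

from __future__ import annotations

import io
import logging
import os
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_KEGG_CLASSES",
    "load_kegg_map",
    "unique_class_sets",
    "load_gene_set",
    "annotate_gene_models",
]

DEFAULT_KEGG_CLASSES = (
    "Metabolism",
    "Environmental Information Processing",
    "Genetic Information Processing",
    "Cellular Processes",
    "Organismal Systems",
)


def _lines(source) -> Iterator[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        yield from source
    else:
        yield from source


def load_kegg_map(source, vocabulary: Sequence[str] = DEFAULT_KEGG_CLASSES) -> dict:
    """Load a gene_id -> set-of-classes mapping from a two-column TSV.

    Repeated rows for a gene union into its class set. A class outside the
    configured vocabulary is a hard error naming the offending row.
    """
    vocab = set(vocabulary)
    assignment: dict = {}
    for lineno, line in enumerate(_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"kegg map line {lineno}: expected gene_id<TAB>class, got {line!r}")
        gene_id, cls = parts[0].strip(), parts[1].strip()
        if cls not in vocab:
            raise ValueError(f"kegg map line {lineno}: unknown class {cls!r} for gene {gene_id!r}")
        assignment.setdefault(gene_id, set()).add(cls)
    return assignment


def unique_class_sets(
    assignment: Mapping[str, set], vocabulary: Sequence[str] = DEFAULT_KEGG_CLASSES
) -> dict:
    """Per-class lists of genes assigned to exactly that one class.

    Multi-class genes appear in no list; gene order follows the mapping's
    insertion order.
    """
    out = {cls: [] for cls in vocabulary}
    for gene_id, classes in assignment.items():
        if len(classes) == 1:
            (cls,) = classes
            if cls in out:
                out[cls].append(gene_id)
    return out


def load_gene_set(source, known_ids: Iterable[str]) -> set:
    """Load a focal gene set (one id per line, '#' comments ignored).

    Ids absent from ``known_ids`` are dropped with a warning; an empty
    resulting set is an error because a focal-set analysis needs at least
    one gene.
    """
    known = set(known_ids)
    out: set = set()
    for line in _lines(source):
        gene_id = line.split("#", 1)[0].strip()
        if not gene_id:
            continue
        if gene_id in known:
            out.add(gene_id)
        else:
            logger.warning("focal set id %r not in known gene ids, dropped", gene_id)
    if not out:
        raise ValueError("focal gene set is empty after filtering against known ids")
    return out


def annotate_gene_models(genes, assignment: Mapping[str, set] = None, focal: set = None) -> None:
    """Attach class labels and focal flags to GeneModels in place."""
    for g in genes:
        if assignment is not None and g.gene_id in assignment:
            g.kegg_classes = set(assignment[g.gene_id])
        if focal is not None:
            g.in_focal_set = g.gene_id in focal
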