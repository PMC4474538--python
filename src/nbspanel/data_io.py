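"""Mutation calls, gene panels and clinical tables: I/O and binary coding.

A tumor's mutation profile is coded as a 0/1 vector over genes: 1 if the
gene carries at least one *functional* somatic mutation (non-synonymous,
splice-site or stop-codon-affecting), 0 otherwise.  Synonymous mutations and
mutations in intronic/intergenic regions are non-functional and never set a
bit.  Samples with too little mutation signal are treated as outliers:
in *full* (exome) mode a sample must have at least 6 mutated genes, in
*panel* mode at least 1 mutated gene inside the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "BinaryMutationMatrix",
    "GenePanel",
    "FUNCTIONAL_CLASSES",
    "NONFUNCTIONAL_CLASSES",
    "is_functional",
    "read_mutations",
    "read_panel",
    "read_clinical",
    "binarize",
    "filter_samples",
    "apply_panel",
    "MIN_FULL_MUTATIONS",
    "MIN_PANEL_MUTATIONS",
]

# Controlled vocabulary mapping common MAF Variant_Classification strings
# (lower-cased) to the functional / non-functional dichotomy.  Editable:
# callers may pass their own sets to is_functional / binarize.
FUNCTIONAL_CLASSES: frozenset[str] = frozenset(
    {
        "missense",
        "missense_mutation",
        "nonsense",
        "nonsense_mutation",
        "splice_site",
        "nonstop",
        "nonstop_mutation",
        "frame_shift_del",
        "frame_shift_ins",
        "in_frame_del",
        "in_frame_ins",
        "translation_start_site",
    }
)

NONFUNCTIONAL_CLASSES: frozenset[str] = frozenset(
    {
        "silent",
        "synonymous",
        "intron",
        "intergenic",
        "igr",
        "3'utr",
        "5'utr",
        "3'flank",
        "5'flank",
        "rna",
    }
)

#: Minimum mutated genes per sample retained in full-exome mode.
MIN_FULL_MUTATIONS = 6
#: Minimum mutated panel genes per sample retained in panel mode.
MIN_PANEL_MUTATIONS = 1


def _norm_gene(symbol: str) -> str:
    # uppercase exact match after trimming; no alias resolution
    return symbol.strip().upper()


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call: sample, gene symbol, variant class."""

    sample_id: str
    gene: str
    variant_class: str

    def __post_init__(self) -> None:
        if not self.sample_id or not self.gene:
            raise ValueError("sample_id and gene must be non-empty")


@dataclass
class BinaryMutationMatrix:
    """Gene x patient 0/1 matrix with ordered gene and sample identifiers.

    ``values[i, j] == 1`` iff gene ``genes[i]`` carries at least one
    functional mutation in sample ``samples[j]``.
    """

    values: np.ndarray
    genes: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BinaryMutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            values=df.to_numpy(dtype=np.int8),
            genes=[str(g) for g in df.index],
            samples=[str(s) for s in df.columns],
        )


@dataclass
class GenePanel:
    """A named set of pre-selected cancer gene symbols."""

    name: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.genes = frozenset(_norm_gene(g) for g in self.genes)
        if not self.genes:
            raise ValueError(f"panel {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return _norm_gene(gene) in self.genes


def is_functional(
    variant_class: str,
    *,
    strict: bool = True,
    functional: frozenset[str] = FUNCTIONAL_CLASSES,
    nonfunctional: frozenset[str] = NONFUNCTIONAL_CLASSES,
) -> bool:
    """Classify a variant class as functional (sets a mutation bit) or not.

    Functional classes are the non-synonymous, splice-site and stop-codon
    categories; silent/intronic/intergenic classes are non-functional.
    Unrecognized classes raise in strict mode (default) and return False
    with a logged warning otherwise.
    """
    key = variant_class.strip().lower()
    if key in functional:
        return True
    if key in nonfunctional:
        return False
    if strict:
        accepted = sorted(functional | nonfunctional)
        raise ValueError(
            f"unrecognized variant class {variant_class!r}; accepted values: "
            + ", ".join(accepted)
        )
    logger.warning("unrecognized variant class %r treated as non-functional", variant_class)
    return False


def read_mutations(
    path: str | Path,
    *,
    sample_col: str = "Tumor_Sample_Barcode",
    gene_col: str = "Hugo_Symbol",
    class_col: str = "Variant_Classification",
) -> list[MutationRecord]:
    """Read a MAF-like tab-separated mutation table into records.

    Only the sample / gene / variant-class columns are used; other MAF
    columns are ignored.  Unknown variant classes are preserved in the
    records (classification happens at binarization time) but flagged here.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in (sample_col, gene_col, class_col):
        if col not in df.columns:
            raise ValueError(f"mutation file {path} is missing required column {col!r}")
    records = [
        MutationRecord(sample_id=str(s), gene=_norm_gene(str(g)), variant_class=str(c))
        for s, g, c in zip(df[sample_col], df[gene_col], df[class_col])
    ]
    known = FUNCTIONAL_CLASSES | NONFUNCTIONAL_CLASSES
    unknown = {r.variant_class for r in records if r.variant_class.strip().lower() not in known}
    if unknown:
        logger.warning("mutation file %s contains unknown variant classes: %s", path, sorted(unknown))
    return records


def read_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Read a gene panel: one symbol per line, ``#`` comments allowed."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(_norm_gene(line))
    return GenePanel(name=name or Path(path).stem, genes=frozenset(genes))


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical table: sample_id, time (days), event in {0,1},
    plus optional grade / stage categoricals."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical file {path} is missing required column {col!r}")
    if (df["time"] < 0).any():
        raise ValueError("clinical times must be non-negative")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")
    return df


def binarize(
    records: Sequence[MutationRecord],
    gene_universe: Sequence[str],
    *,
    strict: bool = False,
) -> BinaryMutationMatrix:
    """Code mutation records into a gene x patient 0/1 matrix.

    Entry (g, s) is 1 iff sample s has at least one functional record for
    gene g.  Records for genes outside ``gene_universe`` are dropped with a
    logged count.  Sample order follows first appearance in ``records``.
    """
    if not records:
        raise ValueError("no mutation records to binarize")
    genes = [_norm_gene(g) for g in gene_universe]
    if len(set(genes)) != len(genes):
        raise ValueError("gene_universe contains duplicate symbols")
    gene_idx = {g: i for i, g in enumerate(genes)}

    samples: list[str] = []
    sample_idx: dict[str, int] = {}
    for r in records:
        if r.sample_id not in sample_idx:
            sample_idx[r.sample_id] = len(samples)
            samples.append(r.sample_id)

    values = np.zeros((len(genes), len(samples)), dtype=np.int8)
    dropped = 0
    for r in records:
        if not is_functional(r.variant_class, strict=strict):
            continue
        gi = gene_idx.get(r.gene)
        if gi is None:
            dropped += 1
            continue
        values[gi, sample_idx[r.sample_id]] = 1
    if dropped:
        logger.info("binarize: dropped %d functional records outside the gene universe", dropped)
    return BinaryMutationMatrix(values=values, genes=genes, samples=samples)


def apply_panel(matrix: BinaryMutationMatrix, panel: GenePanel) -> BinaryMutationMatrix:
    """Restrict the matrix rows to panel genes, preserving row order."""
    keep = [i for i, g in enumerate(matrix.genes) if g in panel.genes]
    if not keep:
        raise ValueError(
            f"panel {panel.name!r} shares no genes with the mutation matrix"
        )
    logger.info("apply_panel: %d of %d panel genes present in matrix", len(keep), len(panel))
    return BinaryMutationMatrix(
        values=matrix.values[keep, :],
        genes=[matrix.genes[i] for i in keep],
        samples=list(matrix.samples),
    )


def filter_samples(
    matrix: BinaryMutationMatrix,
    mode: str = "full",
    panel: GenePanel | None = None,
    *,
    min_full: int = MIN_FULL_MUTATIONS,
    min_panel: int = MIN_PANEL_MUTATIONS,
) -> BinaryMutationMatrix:
    """Discard outlier samples with too few mutated genes.

    ``mode="full"`` keeps samples with at least ``min_full`` (default 6)
    mutated genes.  ``mode="panel"`` first restricts rows to the panel and
    then keeps samples with at least ``min_panel`` (default 1) mutated
    panel genes; the returned matrix is the restricted one.
    """
    if mode == "full":
        working = matrix
        threshold = min_full
    elif mode == "panel":
        if panel is None:
            raise ValueError("panel mode requires a GenePanel")
        working = apply_panel(matrix, panel)
        threshold = min_panel
    else:
        raise ValueError(f"unknown filtering mode {mode!r}; use 'full' or 'panel'")

    colsums = working.values.sum(axis=0)
    keep = np.flatnonzero(colsums >= threshold)
    if keep.size == 0:
        raise ValueError(
            f"all {working.n_samples} samples discarded by the {mode!r} filter "
            f"(threshold {threshold}); inspect the input matrix"
        )
    logger.info(
        "filter_samples(%s): retained %d of %d samples (threshold %d)",
        mode, keep.size, working.n_samples, threshold,
    )
    return BinaryMutationMatrix(
        values=working.values[:, keep],
        genes=list(working.genes),
        samples=[working.samples[j] for j in keep],
    )
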