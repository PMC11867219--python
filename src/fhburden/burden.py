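"""Per-gene carrier status from per-variant genotypes.

Burden testing collapses the qualifying variants of a gene into a single 0/1
carrier indicator per sample: G_i = 1 iff the sample carries at least one
minor allele across the included variants.  Two variant-inclusion rules are
provided: an allele-frequency filter requiring the stored (reference-panel)
and in-sample frequencies both strictly below a threshold, and the
NMD-escape rule that removes protein-truncating variants in the last coding
exon or the final 50 bp of the penultimate exon, where a premature stop
generally escapes nonsense-mediated decay and the transcript is not degraded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExonStructure",
    "BurdenVector",
    "collapse_burden",
    "nmd_escape_excluded",
    "rare_variant_filter",
]

NMD_ESCAPE_WINDOW_BP = 50


class GenotypeMatrix:
    """Sample x variant allele-dosage matrix with per-variant annotation.

    `calls` holds dosages 0/1/2 with NaN for missing; `variants` is a frame
    indexed by variant id with columns gene, chrom, pos (1-based) and af.
    Every variant maps to exactly one gene.
    """

    def __init__(self, samples, variants: pd.DataFrame, calls: np.ndarray):
        self.samples = list(samples)
        variants = variants.copy()
        required = ["gene", "chrom", "pos", "af"]
        missing = [c for c in required if c not in variants.columns]
        if missing:
            raise ValueError(f"variant table is missing columns: {missing}")
        if variants.index.has_duplicates:
            raise ValueError("variant ids must be unique")
        calls = np.asarray(calls, dtype=float)
        if calls.shape != (len(self.samples), len(variants)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.samples)} samples x {len(variants)} variants"
            )
        finite = calls[~np.isnan(calls)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        if ((variants["af"] < 0) | (variants["af"] > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        self.variants = variants
        self.calls = calls

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def variant_ids(self, gene: str | None = None) -> list[str]:
        if gene is None:
            return list(self.variants.index)
        sub = self.variants.index[self.variants["gene"] == gene]
        if sub.empty and gene not in set(self.variants["gene"]):
            raise KeyError(f"unknown gene id {gene!r}")
        return list(sub)

    def in_sample_af(self) -> pd.Series:
        """Minor-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            alleles = np.nansum(self.calls, axis=0)
        n_called = np.sum(~np.isnan(self.calls), axis=0)
        af = np.divide(alleles, 2.0 * n_called, out=np.full(len(self.variants), np.nan),
                       where=n_called > 0)
        return pd.Series(af, index=self.variants.index, name="in_sample_af")


@dataclass(frozen=True)
class ExonStructure:
    """Ordered coding exons of one gene, 1-based inclusive, in transcription
    order (5' to 3' on the coding strand)."""

    gene: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene}: at least one exon required")
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"gene {self.gene}: exon [{start}, {end}] is inverted")
        spans = sorted(self.exons)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.gene}: exons overlap")
        # transcription order: genomic coordinates increase on +, decrease on -
        starts = [s for s, _ in self.exons]
        ordered = starts == sorted(starts) if self.strand == "+" else \
            starts == sorted(starts, reverse=True)
        if len(self.exons) > 1 and not ordered:
            raise ValueError(f"gene {self.gene}: exons are not in transcription order")


@dataclass
class BurdenVector:
    """Per-sample 0/1 carrier indicator for one gene."""

    gene: str
    sample_ids: list[str]
    carrier: np.ndarray
    n_missing_calls: int = 0
    included_variants: list[str] = field(default_factory=list)

    @property
    def n_carriers(self) -> int:
        return int(np.sum(self.carrier))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "gene": self.gene,
                             "carrier": self.carrier.astype(int)})


def collapse_burden(matrix: GenotypeMatrix, gene: str, included,
                    missing_as_noncarrier: bool = True) -> BurdenVector:
    """Collapse the included variants of one gene to a carrier indicator.

    G_i = 1 iff any included dosage is > 0.  Missing dosages count as 0
    (non-carrier evidence) by default, with the number of missing calls
    recorded; `missing_as_noncarrier=False` drops samples with any missing
    included call instead.
    """
    gene_variants = set(matrix.variant_ids(gene))
    included = list(included)
    if not included:
        raise ValueError(f"gene {gene}: empty included-variant set")
    outside = [v for v in included if v not in gene_variants]
    if outside:
        raise ValueError(f"gene {gene}: variants {outside} do not belong to the gene")
    cols = [matrix.variants.index.get_loc(v) for v in included]
    sub = matrix.calls[:, cols]
    n_missing = int(np.isnan(sub).sum())
    carrier = np.nansum(sub, axis=1) > 0
    samples = matrix.samples
    if not missing_as_noncarrier and n_missing:
        keep = ~np.isnan(sub).any(axis=1)
        carrier = carrier[keep]
        samples = [s for s, k in zip(samples, keep) if k]
    return BurdenVector(gene=gene, sample_ids=list(samples),
                        carrier=carrier.astype(bool), n_missing_calls=n_missing,
                        included_variants=included)


def nmd_escape_excluded(position: int, exons: ExonStructure) -> bool:
    """Whether a PTV at `position` should be excluded as escaping NMD.

    True iff the position falls in the last coding exon, or within the final
    50 bp (measured along the coding strand, inclusive of the 3'-most base) of
    the penultimate exon.  Single-exon genes escape NMD entirely, so every
    exonic position is excluded.  Positions in no exon are an error — the
    rule is defined only for exonic variants.
    """
    hit = None
    for idx, (start, end) in enumerate(exons.exons):
        if start <= position <= end:
            hit = idx
            break
    if hit is None:
        raise ValueError(
            f"position {position} lies in no exon of gene {exons.gene}; "
            "the NMD-escape rule applies only to exonic positions"
        )
    n = len(exons.exons)
    if hit == n - 1:
        return True
    if hit == n - 2:
        start, end = exons.exons[hit]
        if exons.strand == "+":
            return position >= end - (NMD_ESCAPE_WINDOW_BP - 1)
        return position <= start + (NMD_ESCAPE_WINDOW_BP - 1)
    return False


def rare_variant_filter(matrix: GenotypeMatrix, af_threshold: float = 0.001):
    """Variants rare in both the stored reference frequency and in-sample.

    Both frequencies must be strictly below the threshold; a variant at
    exactly the threshold is excluded.  In-sample frequency is computed over
    non-missing calls only.
    """
    if not 0.0 < af_threshold <= 1.0:
        raise ValueError("af_threshold must be in (0, 1]")
    stored = matrix.variants["af"]
    insample = matrix.in_sample_af()
    keep = (stored < af_threshold) & (insample.fillna(0.0) < af_threshold)
    return set(stored.index[keep])
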