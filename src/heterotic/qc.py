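"""Genotype matrix container, file I/O and marker quality-control filters.

Genotypes are biallelic SNP calls coded as the dosage of the alternative
allele: 0 (homozygous reference), 1 (heterozygous), 2 (homozygous
alternative), with ``-1`` marking a missing call.  The QC cascade mirrors
the standard marker-retention workflow for genotyping-by-sequencing panels
of inbred lines: a call-rate filter, a missingness filter, and an
allele-frequency filter, applied in that fixed order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1
NUCLEOTIDES = frozenset("ACGT")
#: Unordered nucleotide pairs, in reporting order.
SUBSTITUTION_CLASSES = ("A/C", "A/G", "A/T", "C/G", "C/T", "G/T")
#: Purine-purine / pyrimidine-pyrimidine exchanges.
TRANSITIONS = frozenset({"A/G", "C/T"})


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype input (parse errors, multi-allelic records)."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic markers dosage matrix.

    Attributes
    ----------
    individual_ids : list of str
        Unique row labels.
    marker_ids : list of str
        Unique column labels.
    alleles : list of (str, str)
        Per marker the (reference, alternative) allele labels.  Dosage
        counts the alternative allele.
    calls : ndarray of int8, shape (n_individuals, n_markers)
        Values in {0, 1, 2} or ``MISSING``.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    alleles: list[tuple[str, str]]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match calls rows")
        if len(self.marker_ids) != m or len(self.alleles) != m:
            raise ValueError("marker_ids/alleles length does not match calls columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker ids are not unique")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1, 2 or missing (-1)")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return (self.calls != MISSING).mean(axis=0)

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-marker alternative-allele frequency over non-missing calls."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs, self.calls, 0).sum(axis=0) / (2.0 * n_obs)

    def subset_markers(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            marker_ids=[self.marker_ids[i] for i in index],
            alleles=[self.alleles[i] for i in index],
            calls=self.calls[:, index],
        )

    # ------------------------------------------------------------------ I/O

    def to_dosage_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.calls.astype(float), index=self.individual_ids, columns=self.marker_ids
        )
        return df.mask(df < 0)

    def write_dosage_csv(self, path: str | Path) -> None:
        """Write individuals x markers CSV with cells 0/1/2 and blank for missing.

        Allele labels are not representable in this format; use the VCF
        writer when they matter downstream.
        """
        self.to_dosage_frame().to_csv(path, index_label="individual", float_format="%.0f")

    def write_vcf(self, path: str | Path) -> None:
        """Write a minimal VCF 4.2 with GT fields on a single pseudo-contig."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##contig=<ID=1>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.individual_ids)
                + "\n"
            )
            gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for j, mid in enumerate(self.marker_ids):
                ref, alt = self.alleles[j]
                gts = "\t".join(gt_code[int(c)] for c in self.calls[:, j])
                fh.write(f"1\t{j + 1}\t{mid}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a dosage CSV.

    Heterozygous calls map to dosage 1 regardless of phasing; multi-allelic
    records are rejected by name.  Dosage CSVs carry no allele labels, so
    markers read from that dialect get the placeholder pair ``("N", "N")``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_csv":
        return _read_dosage_csv(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise GenotypeFormatError(f"cannot parse VCF {path}: {exc}") from exc
    individuals = list(vcf.samples)
    marker_ids: list[str] = []
    alleles: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    recode = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeFormatError(
                f"multi-allelic record not supported: marker {var.ID or var.POS}"
            )
        marker_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        alleles.append((var.REF, var.ALT[0]))
        columns.append(recode[var.gt_types])
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, marker_ids, alleles, calls)


def _read_dosage_csv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:
        raise GenotypeFormatError(f"cannot parse dosage CSV {path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(values), MISSING, values)
    if not np.isin(calls, (0, 1, 2, MISSING)).all():
        raise GenotypeFormatError(f"dosage CSV {path} contains values outside 0/1/2/NA")
    return GenotypeMatrix(
        individual_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
        alleles=[("N", "N")] * df.shape[1],
        calls=calls.astype(np.int8),
    )


# ------------------------------------------------------------------ filters


@dataclass
class QcReport:
    """Marker counts and dropped ids along the three-stage filter cascade."""

    n_input_markers: int
    n_after_callrate: int
    n_after_missing: int
    n_after_freq: int
    dropped_callrate: list[str] = field(default_factory=list)
    dropped_missing: list[str] = field(default_factory=list)
    dropped_freq: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = (
            self.n_input_markers,
            self.n_after_callrate,
            self.n_after_missing,
            self.n_after_freq,
        )
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError("filter-stage counts must be non-increasing")


def filter_markers(
    g: GenotypeMatrix,
    min_call_rate: float = 0.80,
    max_missing: float = 0.10,
    freq_bounds: tuple[float, float] = (0.05, 0.95),
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the marker-retention cascade in its fixed order.

    1. retain markers with call rate strictly above ``min_call_rate``;
    2. drop markers with missing fraction strictly above ``max_missing``;
    3. retain markers whose alternative-allele frequency lies in the
       closed interval ``freq_bounds`` (equivalent to a minor-allele
       frequency floor for biallelic loci).
    """
    for name, v in (("min_call_rate", min_call_rate), ("max_missing", max_missing)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    lo, hi = freq_bounds
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"freq_bounds must be ordered within [0, 1], got {freq_bounds}")

    n_input = g.n_markers
    ids = np.asarray(g.marker_ids)

    keep1 = g.call_rate() > min_call_rate
    dropped_callrate = list(ids[~keep1])
    g1 = g.subset_markers(np.flatnonzero(keep1))

    keep2 = g1.missing_fraction() <= max_missing
    dropped_missing = list(np.asarray(g1.marker_ids)[~keep2])
    g2 = g1.subset_markers(np.flatnonzero(keep2))

    freq = g2.alt_freq()
    with np.errstate(invalid="ignore"):
        keep3 = (freq >= lo) & (freq <= hi)
    dropped_freq = list(np.asarray(g2.marker_ids)[~keep3])
    g3 = g2.subset_markers(np.flatnonzero(keep3))

    notes = []
    if g3.n_markers == 0:
        notes.append("no markers survive the QC cascade")
        warnings.warn(notes[-1], stacklevel=2)
    report = QcReport(
        n_input_markers=n_input,
        n_after_callrate=g1.n_markers,
        n_after_missing=g2.n_markers,
        n_after_freq=g3.n_markers,
        dropped_callrate=dropped_callrate,
        dropped_missing=dropped_missing,
        dropped_freq=dropped_freq,
        warnings=notes,
    )
    return g3, report


# ------------------------------------------------------- substitution classes


@dataclass
class SubstitutionSpectrum:
    """Counts of markers per unordered allele pair, with transition bookkeeping."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def transition_count(self) -> int:
        return sum(v for k, v in self.counts.items() if k in TRANSITIONS)

    @property
    def transition_fraction(self) -> float:
        return self.transition_count / self.total if self.total else float("nan")

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, name="count")


def substitution_spectrum(g: GenotypeMatrix) -> SubstitutionSpectrum:
    """Tally markers by unordered reference/alternative nucleotide pair."""
    counts = dict.fromkeys(SUBSTITUTION_CLASSES, 0)
    for mid, (ref, alt) in zip(g.marker_ids, g.alleles):
        if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
            raise ValueError(f"marker {mid} has non-nucleotide alleles ({ref}, {alt})")
        key = "/".join(sorted((ref, alt)))
        if key not in counts:
            raise ValueError(f"marker {mid} is not a substitution: alleles ({ref}, {alt})")
        counts[key] += 1
    return SubstitutionSpectrum(counts)
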