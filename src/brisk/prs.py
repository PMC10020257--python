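"""Multiplicative polygenic risk score with Hardy-Weinberg normalization.

Each SNP contributes the factor ``r**g / mu(p, r)`` where ``g`` is the
risk-allele count, ``r`` the per-allele odds ratio and

    mu(p, r) = (1-p)^2 + 2 p (1-p) r + p^2 r^2

the population-mean genotype risk under Hardy-Weinberg equilibrium at
risk-allele frequency ``p``.  The product over SNPs therefore has population
mean 1 (loci independent), so the score plugs directly into the
multiplicative relative-risk model as another centered component.

Missing genotypes contribute factor 1 — i.e. the population mean — which
keeps scores centered and the sample size constant instead of dropping
women with incomplete genotyping.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "SnpWeight",
    "GenotypeVector",
    "PrsResult",
    "hwe_mean_factor",
    "snp_factor",
    "prs_score",
    "load_weight_table",
    "genotypes_from_vcf",
    "genotypes_from_dosage_csv",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SnpWeight:
    """Per-variant weight: risk allele, its frequency ``p`` and per-allele
    odds ratio ``r``."""

    variant_id: str
    risk_allele: str
    p: float
    r: float
    chrom: str | None = None
    pos: int | None = None
    other_allele: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise InputError(f"{self.variant_id}: frequency {self.p} outside (0, 1)")
        if self.r <= 0:
            raise InputError(f"{self.variant_id}: odds ratio {self.r} must be > 0")

    @property
    def palindromic(self) -> bool:
        """A/T or C/G pairs are strand-ambiguous."""
        other = self.other_allele
        return other is not None and _COMPLEMENT.get(self.risk_allele) == other


@dataclass
class GenotypeVector:
    """Risk-allele counts per variant id; ``None`` marks a missing call."""

    counts: dict[str, int | None] = field(default_factory=dict)
    sample: str | None = None

    def get(self, variant_id: str) -> int | None:
        return self.counts.get(variant_id)

    def __setitem__(self, variant_id: str, g: int | None) -> None:
        if g is not None and g not in (0, 1, 2):
            raise InputError(f"{variant_id}: allele count {g} not in {{0, 1, 2}}")
        self.counts[variant_id] = g


@dataclass(frozen=True)
class PrsResult:
    score: float
    n_used: int
    n_missing: int


def hwe_mean_factor(p: float, r: float) -> float:
    """Population mean of ``r**g`` over HWE genotype frequencies."""
    if not 0.0 < p < 1.0:
        raise InputError(f"frequency {p} outside (0, 1)")
    if r <= 0:
        raise InputError(f"odds ratio {r} must be > 0")
    q = 1.0 - p
    return q * q + 2.0 * p * q * r + p * p * r * r


def snp_factor(g: int | None, weight: SnpWeight) -> float:
    """Normalized per-SNP factor ``r**g / mu``; exactly 1 for missing ``g``."""
    if g is None:
        return 1.0
    if g not in (0, 1, 2):
        raise InputError(f"allele count {g} not in {{0, 1, 2}}")
    return weight.r**g / hwe_mean_factor(weight.p, weight.r)


def prs_score(genotypes: GenotypeVector, weights: Sequence[SnpWeight]) -> PrsResult:
    """Product of per-SNP factors over the whole weight table.

    Genotyped variants absent from the weight table are ignored (logged);
    weight-table variants absent from the genotypes count as missing.
    """
    if not weights:
        raise ConfigurationError("empty SNP weight table")
    known = {w.variant_id for w in weights}
    extra = [v for v in genotypes.counts if v not in known]
    if extra:
        logger.info("ignoring %d genotyped variants not in the weight table", len(extra))
    score = 1.0
    n_used = 0
    for w in weights:
        g = genotypes.get(w.variant_id)
        score *= snp_factor(g, w)
        if g is not None:
            n_used += 1
    return PrsResult(score=score, n_used=n_used, n_missing=len(weights) - n_used)


# ---------------------------------------------------------------------------
# File input
# ---------------------------------------------------------------------------

_WEIGHT_COLUMNS = ("variant_id", "chrom", "pos", "risk_allele", "other_allele", "freq", "or")


def load_weight_table(path: str) -> list[SnpWeight]:
    """Read a tab-separated SNP weight table.

    Expected header: ``variant_id chrom pos risk_allele other_allele freq or``.
    """
    weights: list[SnpWeight] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_WEIGHT_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ConfigurationError(
                f"{path}: weight table missing columns {sorted(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            vid = row["variant_id"]
            if vid in seen:
                raise ConfigurationError(f"{path}:{lineno}: duplicate variant {vid}")
            seen.add(vid)
            try:
                weights.append(
                    SnpWeight(
                        variant_id=vid,
                        chrom=row["chrom"] or None,
                        pos=int(row["pos"]) if row["pos"] else None,
                        risk_allele=row["risk_allele"].upper(),
                        other_allele=(row["other_allele"] or "").upper() or None,
                        p=float(row["freq"]),
                        r=float(row["or"]),
                    )
                )
            except (ValueError, InputError) as exc:
                raise ConfigurationError(f"{path}:{lineno}: {exc}") from exc
    if not weights:
        raise ConfigurationError(f"{path}: weight table is empty")
    return weights


def _resolve_orientation(weight: SnpWeight, ref: str, alt: str) -> str | None:
    """Decide whether the risk allele is carried by REF or ALT.

    Returns ``"ref"``, ``"alt"`` or ``None`` when the match is ambiguous.
    Palindromic (A/T, C/G) variants are accepted on allele identity only when
    the risk-allele frequency is informative (|p - 0.5| > 0.1); otherwise the
    strand cannot be resolved and the variant is treated as missing.
    """
    ref = ref.upper()
    alt = alt.upper()
    risk = weight.risk_allele
    if weight.palindromic and abs(weight.p - 0.5) <= 0.1:
        return None
    if risk == alt:
        return "alt"
    if risk == ref:
        return "ref"
    # try strand flip
    flipped = _COMPLEMENT.get(risk)
    if flipped == alt:
        return "alt"
    if flipped == ref:
        return "ref"
    return None


def genotypes_from_vcf(path: str, weights: Sequence[SnpWeight]) -> list[GenotypeVector]:
    """Extract risk-allele counts for every sample in a VCF.

    Variants are matched by id, falling back to (chrom, pos, allele pair).
    Allele orientation is resolved so that ``g`` always counts risk alleles;
    unmatched or ambiguous weight entries are left missing (with a warning).
    """
    from cyvcf2 import VCF  # deferred: keeps import light for non-VCF users

    try:
        vcf = VCF(path)
    except OSError as exc:  # pragma: no cover - cyvcf2 raises on bad path
        raise InputError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    vectors = [GenotypeVector(sample=s) for s in samples]
    by_id = {w.variant_id: w for w in weights}
    by_locus = {
        (w.chrom, w.pos): w for w in weights if w.chrom is not None and w.pos is not None
    }
    for variant in vcf:
        weight = by_id.get(variant.ID) or by_locus.get(
            (str(variant.CHROM), int(variant.POS))
        )
        if weight is None or len(variant.ALT) != 1:
            continue
        orientation = _resolve_orientation(weight, variant.REF, variant.ALT[0])
        if orientation is None:
            logger.warning(
                "%s: ambiguous allele match for %s (%s/%s), treated as missing",
                path,
                weight.variant_id,
                variant.REF,
                variant.ALT[0],
            )
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for i, gt in enumerate(variant.gt_types):
            if gt == 2:
                continue
            alt_count = {0: 0, 1: 1, 3: 2}[gt]
            g = alt_count if orientation == "alt" else 2 - alt_count
            vectors[i][weight.variant_id] = g
    n_matched = len({v for vec in vectors for v in vec.counts})
    logger.info("matched %d of %d weight-table variants in %s", n_matched, len(weights), path)
    return vectors


def genotypes_from_dosage_csv(path: str) -> list[GenotypeVector]:
    """Read a samples x variants matrix of 0/1/2 risk-allele counts.

    First column is the sample id; header row carries variant ids; empty
    cells are missing calls.
    """
    vectors: list[GenotypeVector] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or len(header) < 2:
            raise InputError(f"{path}: dosage matrix needs sample id + variant columns")
        variant_ids = header[1:]
        for lineno, row in enumerate(reader, start=2):
            vec = GenotypeVector(sample=row[0])
            for vid, cell in zip(variant_ids, row[1:]):
                if cell == "":
                    vec[vid] = None
                else:
                    try:
                        vec[vid] = int(cell)
                    except (ValueError, InputError) as exc:
                        raise InputError(f"{path}:{lineno}: {exc}") from exc
            vectors.append(vec)
    return vectors
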