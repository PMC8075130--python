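"""Codon-level consequence annotation against a mitochondrial gene model.

Locates SNPs within coding genes, reads the affected codon from the
reference (circular-origin aware), translates reference and mutated codons
under the vertebrate mitochondrial genetic code (NCBI table 2), flags
synonymous changes, and reports the codon-usage molar ratio (frequency per
thousand) for synonymous substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class LocateError(ValueError):
    """Position outside the gene span."""


class ConsistencyError(ValueError):
    """Stated reference allele disagrees with the reference sequence."""


class UnsupportedVariantError(ValueError):
    """Annotation supports SNPs only."""


@dataclass
class GeneModel:
    """One gene span, 1-based inclusive; ``wrap=True`` genes cross the
    circular origin (start > end, coordinates unrolled past length L)."""

    gene: str
    start: int
    end: int
    strand: str  # "+" | "-"
    phase_offset: int = 0
    coding: bool = True
    wrap: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.phase_offset not in (0, 1, 2):
            raise ValueError("phase_offset must be 0, 1 or 2")
        if self.start > self.end and not self.wrap:
            raise ValueError(f"gene {self.gene}: start > end without wrap flag")

    def span_length(self, genome_length: int | None = None) -> int:
        if not self.wrap:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError("wrap gene needs genome_length")
        return genome_length - self.start + 1 + self.end

    def contains(self, position: int, genome_length: int | None = None) -> bool:
        if not self.wrap:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end


def validate_gene_model(gm: GeneModel, genome_length: int) -> None:
    span = gm.span_length(genome_length)
    if gm.coding and (span - gm.phase_offset) % 3 != 0:
        raise ValueError(
            f"gene {gm.gene}: coding span {span} minus phase {gm.phase_offset} "
            "not divisible by 3"
        )


def read_gene_model_tsv(path) -> list[GeneModel]:
    """Read ``gene<TAB>start<TAB>end<TAB>strand<TAB>phase<TAB>coding[<TAB>wrap]``."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("gene\t"):
                continue
            parts = line.split("\t")
            genes.append(
                GeneModel(
                    gene=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    strand=parts[3],
                    phase_offset=int(parts[4]),
                    coding=parts[5].strip().lower() in ("1", "true", "yes", "coding"),
                    wrap=len(parts) > 6 and parts[6].strip().lower() in ("1", "true", "yes"),
                )
            )
    return genes


def vertebrate_mito_code() -> dict[str, str]:
    """Codon -> amino-acid map under NCBI translation table 2 ('*' = stop)."""
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[2]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    assert len(code) == 64
    return code


def read_code_table_tsv(path) -> dict[str, str]:
    """Read a ``codon<TAB>amino_acid`` table ('*' for stop); must cover all 64."""
    code: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("codon\t"):
                continue
            codon, aa = line.split("\t")[:2]
            code[codon.strip().upper()] = aa.strip()
    if len(code) != 64:
        raise ValueError(f"code table must define all 64 codons, got {len(code)}")
    return code


def read_usage_table_tsv(path) -> dict[str, float]:
    """Read a ``codon<TAB>frequency_per_thousand`` codon-usage table."""
    usage: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("codon\t"):
                continue
            codon, freq = line.split("\t")[:2]
            usage[codon.strip().upper()] = float(freq)
    return usage


@dataclass
class ConsequenceAnnotation:
    position: int
    gene: str  # gene name or "intergenic"
    codon_index: int | None = None
    codon_position: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    synonymous: bool | None = None
    codon_usage_ratio: float | None = None


def _unrolled_offset(position: int, gm: GeneModel, genome_length: int) -> int:
    """0-based offset of ``position`` along the gene's 5'->3' reading frame."""
    if not gm.contains(position, genome_length):
        raise LocateError(f"position {position} outside gene {gm.gene}")
    if gm.wrap and position <= gm.end:
        linear = genome_length - gm.start + position  # unrolled past origin
    else:
        linear = position - gm.start
    if gm.strand == "+":
        offset = linear - gm.phase_offset
    else:
        offset = gm.span_length(genome_length) - 1 - linear - gm.phase_offset
    if offset < 0:
        raise LocateError(
            f"position {position} lies in the phase offset of gene {gm.gene}"
        )
    return offset


def locate_codon(
    position: int, gm: GeneModel, genome_length: int | None = None
) -> tuple[int, int]:
    """(codon_index, codon_position), both 1-based, for a coding position."""
    if not gm.coding:
        raise LocateError(f"gene {gm.gene} is non-coding")
    offset = _unrolled_offset(position, gm, genome_length or gm.end)
    return offset // 3 + 1, offset % 3 + 1


def _codon_genome_positions(
    codon_index: int, gm: GeneModel, genome_length: int
) -> list[int]:
    """Genome coordinates (5'->3' in the gene frame) of one codon."""
    positions = []
    for codon_pos in (1, 2, 3):
        offset = (codon_index - 1) * 3 + (codon_pos - 1)
        if gm.strand == "+":
            linear = offset + gm.phase_offset
        else:
            linear = gm.span_length(genome_length) - 1 - offset - gm.phase_offset
        p = gm.start + linear
        if p > genome_length:  # wrap past the circular origin
            p -= genome_length
        positions.append(p)
    return positions


def classify_consequence(
    position: int,
    ref: str,
    alt: str,
    gene_models: Sequence[GeneModel],
    reference_seq: str,
    code_table: Mapping[str, str] | None = None,
    usage_table: Mapping[str, float] | None = None,
) -> ConsequenceAnnotation:
    """Annotate one SNP against the gene model.

    Positions outside all genes are returned as ``"intergenic"``; positions
    in non-coding (tRNA/rRNA) genes carry the gene name but no codon fields.
    When a usage table is given, synonymous changes also report the
    alt/ref codon-usage molar ratio.
    """
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        raise UnsupportedVariantError("annotation supports single-base SNPs only")
    L = len(reference_seq)
    if not 1 <= position <= L:
        raise LocateError(f"position {position} outside reference (1..{L})")
    if reference_seq[position - 1] != ref:
        raise ConsistencyError(
            f"reference has {reference_seq[position - 1]} at {position}, call says {ref}"
        )
    code_table = code_table or vertebrate_mito_code()
    hits = [g for g in gene_models if g.contains(position, L)]
    if not hits:
        return ConsequenceAnnotation(position=position, gene="intergenic")
    gm = next((g for g in hits if g.coding), hits[0])
    if not gm.coding:
        return ConsequenceAnnotation(position=position, gene=gm.gene)

    codon_index, codon_position = locate_codon(position, gm, L)
    coords = _codon_genome_positions(codon_index, gm, L)
    bases = [reference_seq[p - 1] for p in coords]
    alt_bases = [alt if p == position else reference_seq[p - 1] for p in coords]
    if gm.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
        alt_bases = [b.translate(_COMPLEMENT) for b in alt_bases]
    ref_codon = "".join(bases)
    alt_codon = "".join(alt_bases)
    try:
        ref_aa = code_table[ref_codon]
        alt_aa = code_table[alt_codon]
    except KeyError as exc:
        raise ValueError(f"codon {exc.args[0]!r} missing from code table") from exc
    synonymous = ref_aa == alt_aa
    ratio = None
    if synonymous and usage_table is not None:
        try:
            ratio = codon_usage_ratio(alt_codon, ref_codon, usage_table)
        except (KeyError, ValueError):
            ratio = None
    return ConsequenceAnnotation(
        position=position,
        gene=gm.gene,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=synonymous,
        codon_usage_ratio=ratio,
    )


def codon_usage_ratio(
    codon_a: str, codon_b: str, usage_table: Mapping[str, float]
) -> float:
    """Molar ratio usage(codon_a) / usage(codon_b), frequencies per thousand."""
    a = usage_table[codon_a.upper()]
    b = usage_table[codon_b.upper()]
    if b <= 0:
        raise ValueError(f"zero/negative usage for denominator codon {codon_b}")
    if a < 0:
        raise ValueError(f"negative usage for codon {codon_a}")
    return a / b
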