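"""Cohort ingestion and the polarized per-site allele-count matrix.

Reads aligned whole-mitogenome consensus FASTA (one fixed-length record per
sample), per-sample VCF variant calls, and a sample->group metadata table;
derives consensus-level variant calls against the reference; applies the
heteroplasmy (minor:major read-ratio) and homopolymer-indel filters; and
builds, for every reference position, per-group allele counts polarized to
the cohort-wide major allele.  Coordinates are 1-based and inclusive
throughout, matching mtDNA (rCRS) convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("mitoscan")

#: two-base IUPAC ambiguity codes, used to represent heteroplasmic consensus
IUPAC2: dict[str, frozenset[str]] = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}
IUPAC2_REV: dict[frozenset[str], str] = {v: k for k, v in IUPAC2.items()}

VALID_BASES = frozenset("ACGT")
VALID_CHARS = VALID_BASES | frozenset("N-") | frozenset(IUPAC2)


class AlignmentError(ValueError):
    """Record length disagrees with the reference/cohort alignment."""


class MetadataError(KeyError):
    """A sample id is missing from the metadata table."""


class AlphabetError(ValueError):
    """A sequence contains a character outside the supported alphabet."""


class DegenerateCohortError(ValueError):
    """A group contributes no countable samples anywhere in the genome."""


@dataclass
class MitoSequence:
    """One aligned consensus mitogenome with its phenotype group label."""

    sample_id: str
    bases: str
    group: str


@dataclass
class VariantCall:
    """A single-sample variant against the reference (1-based position)."""

    sample_id: str
    position: int
    ref_allele: str
    alt_allele: str
    kind: str  # "SNP" | "insertion" | "deletion"
    minor_fraction: float | None = None
    heteroplasmic: bool = False
    masked: bool = False


@dataclass
class SiteCounts:
    """Per-position, per-group allele counts polarized to the major allele."""

    position: int
    major_allele: str
    counts_by_group: dict[str, dict[str, int]]
    polymorphic: bool

    def group_total(self, group: str) -> int:
        return sum(self.counts_by_group[group].values())

    def pooled(self) -> dict[str, int]:
        pooled: dict[str, int] = {}
        for counts in self.counts_by_group.values():
            for allele, n in counts.items():
                pooled[allele] = pooled.get(allele, 0) + n
        return pooled


@dataclass
class CohortConfig:
    """Filtering and counting policy knobs.

    heteroplasmy_min_ratio
        minimum minor:major ratio for a heteroplasmy call (0.25 == 1:4).
    homopolymer_min_run
        shortest single-base reference run inside which indel calls are masked.
    heteroplasmy_policy
        how a heteroplasmic sample-site enters the count matrix:
        ``exclude_site_sample`` drops that sample at that site (default),
        ``count_major`` counts the reference base, ``iupac`` counts the
        ambiguity code itself as an allele.
    multiallelic_delta
        delta definition at sites with >2 alleles (see delta_scan).
    """

    heteroplasmy_min_ratio: float = 0.25
    homopolymer_min_run: int = 5
    heteroplasmy_policy: str = "exclude_site_sample"
    multiallelic_delta: str = "total_variation"

    def __post_init__(self) -> None:
        if not 0 < self.heteroplasmy_min_ratio <= 1:
            raise ValueError("heteroplasmy_min_ratio must be in (0, 1]")
        if self.homopolymer_min_run < 2:
            raise ValueError("homopolymer_min_run must be >= 2")
        if self.heteroplasmy_policy not in (
            "exclude_site_sample",
            "count_major",
            "iupac",
        ):
            raise ValueError(f"unknown heteroplasmy_policy {self.heteroplasmy_policy!r}")
        if self.multiallelic_delta not in ("total_variation", "max_nonmajor"):
            raise ValueError(f"unknown multiallelic_delta {self.multiallelic_delta!r}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_metadata_tsv(path) -> dict[str, str]:
    """Read a ``sample_id<TAB>group`` table (header required)."""
    metadata: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample_id", "group"]:
            raise MetadataError(f"expected header 'sample_id\\tgroup', got {header!r}")
        for line in fh:
            if not line.strip():
                continue
            sample_id, group = line.rstrip("\n").split("\t")[:2]
            metadata[sample_id] = group
    return metadata


def read_reference_fasta(path) -> str:
    """Read a single-record reference FASTA, upper-cased."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise AlignmentError(f"reference FASTA must contain exactly 1 record, got {len(records)}")
    seq = str(records[0].seq).upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise AlphabetError(f"reference contains non-ACGT characters: {sorted(bad)}")
    return seq


def read_aligned_fasta(path, metadata: Mapping[str, str]) -> list[MitoSequence]:
    """Read an aligned cohort FASTA; every record must match the metadata.

    All records must have equal length (they are columns of one alignment
    against the reference); record order is preserved.
    """
    seqs: list[MitoSequence] = []
    length: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        bases = str(rec.seq).upper()
        if length is None:
            length = len(bases)
        elif len(bases) != length:
            raise AlignmentError(
                f"record {rec.id!r} has length {len(bases)}, expected {length}"
            )
        if rec.id not in metadata:
            raise MetadataError(f"sample {rec.id!r} absent from metadata")
        bad = set(bases) - VALID_CHARS
        if bad:
            raise AlphabetError(f"record {rec.id!r} contains {sorted(bad)}")
        seqs.append(MitoSequence(sample_id=rec.id, bases=bases, group=metadata[rec.id]))
    return seqs


def read_vcf_variants(path) -> list[VariantCall]:
    """Read per-sample variant calls from a VCF (POS 1-based, GT per sample).

    Emits one :class:`VariantCall` per sample x ALT allele with a
    non-reference genotype.  The per-sample allele fraction is taken from the
    ``AF`` FORMAT field when present and folded to the minor fraction.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for sample_name, sample in rec.samples.items():
                gt = sample.get("GT")
                if gt is None:
                    continue
                alleles = [a for a in gt if a is not None]
                for alt_index in sorted({a for a in alleles if a > 0}):
                    alt = rec.alleles[alt_index]
                    ref = rec.ref
                    if len(ref) == len(alt) == 1:
                        kind = "SNP"
                    elif len(alt) > len(ref):
                        kind = "insertion"
                    else:
                        kind = "deletion"
                    af = sample.get("AF")
                    if isinstance(af, tuple):
                        af = af[alt_index - 1] if len(af) >= alt_index else None
                    minor = None
                    heteroplasmic = len(set(alleles)) > 1
                    if af is not None:
                        minor = min(float(af), 1.0 - float(af))
                        heteroplasmic = heteroplasmic or 0.0 < float(af) < 1.0
                    if heteroplasmic and minor is None:
                        minor = 0.5
                    calls.append(
                        VariantCall(
                            sample_id=sample_name,
                            position=rec.pos,
                            ref_allele=ref,
                            alt_allele=alt,
                            kind=kind,
                            minor_fraction=minor,
                            heteroplasmic=heteroplasmic,
                        )
                    )
    return calls


# ---------------------------------------------------------------------------
# consensus-level variant derivation
# ---------------------------------------------------------------------------


def calls_from_alignment(
    seqs: Sequence[MitoSequence], reference: str
) -> list[VariantCall]:
    """Diff each aligned consensus against the reference.

    SNPs: sample base in {A,C,G,T} differing from the reference base.
    Deletions: maximal ``-`` runs, anchored at the first gapped position.
    IUPAC two-base codes yield a heteroplasmic call for each non-reference
    base (minor_fraction 0.5 by convention: a consensus code carries no
    read-fraction information).  ``N`` never produces a call.
    """
    bad = set(reference) - VALID_BASES
    if bad:
        raise AlphabetError(f"reference contains non-ACGT characters: {sorted(bad)}")
    calls: list[VariantCall] = []
    L = len(reference)
    ref_codes = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    for seq in seqs:
        if len(seq.bases) != L:
            raise AlignmentError(
                f"sample {seq.sample_id!r} length {len(seq.bases)} != reference {len(reference)}"
            )
        codes = np.frombuffer(seq.bases.encode("ascii"), dtype=np.uint8)
        mismatches = np.flatnonzero(codes != ref_codes)
        k = 0
        while k < len(mismatches):
            i = int(mismatches[k])
            base = seq.bases[i]
            ref = reference[i]
            if base == "-":
                j = i
                while j < L and seq.bases[j] == "-":
                    j += 1
                calls.append(
                    VariantCall(
                        sample_id=seq.sample_id,
                        position=i + 1,
                        ref_allele=reference[i:j],
                        alt_allele="-",
                        kind="deletion",
                    )
                )
                while k < len(mismatches) and mismatches[k] < j:
                    k += 1
                continue
            if base in VALID_BASES:
                if base != ref:
                    calls.append(
                        VariantCall(
                            sample_id=seq.sample_id,
                            position=i + 1,
                            ref_allele=ref,
                            alt_allele=base,
                            kind="SNP",
                        )
                    )
            elif base in IUPAC2:
                for alt in sorted(IUPAC2[base] - {ref}):
                    calls.append(
                        VariantCall(
                            sample_id=seq.sample_id,
                            position=i + 1,
                            ref_allele=ref,
                            alt_allele=alt,
                            kind="SNP",
                            minor_fraction=0.5,
                            heteroplasmic=True,
                        )
                    )
            elif base != "N":
                raise AlphabetError(
                    f"sample {seq.sample_id!r} position {i + 1}: invalid character {base!r}"
                )
            k += 1
    return calls


def heteroplasmy_flag(minor_count: int, major_count: int, cfg: CohortConfig) -> bool:
    """True iff the minor:major ratio reaches the calling threshold (1:4)."""
    if minor_count < 0 or major_count < 0:
        raise ValueError("counts must be non-negative")
    if minor_count == 0 and major_count == 0:
        raise ValueError("undefined ratio: both counts are zero")
    if major_count == 0:
        return True
    return minor_count / major_count >= cfg.heteroplasmy_min_ratio


def homopolymer_run_length(reference: str, position: int) -> int:
    """Length of the single-base reference run containing 1-based position."""
    i = position - 1
    base = reference[i]
    lo = i
    while lo > 0 and reference[lo - 1] == base:
        lo -= 1
    hi = i
    while hi + 1 < len(reference) and reference[hi + 1] == base:
        hi += 1
    return hi - lo + 1


def mask_homopolymer_indels(
    calls: Iterable[VariantCall], reference: str, cfg: CohortConfig
) -> list[VariantCall]:
    """Mask indel calls anchored inside long single-base reference runs.

    Indels within homopolymeric blocks are unreliable and are treated as
    having no effect downstream (masked calls are excluded from the count
    matrix).  SNPs are never masked.
    """
    out: list[VariantCall] = []
    for call in calls:
        if call.kind in ("insertion", "deletion"):
            run = homopolymer_run_length(reference, call.position)
            if run >= cfg.homopolymer_min_run:
                call.masked = True
        out.append(call)
    return out


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

_EXCLUDED = "__excluded__"


def _column_symbol(
    base: str, ref: str, cfg: CohortConfig, deletion_masked: bool
) -> str | None:
    """Resolve one sample's contribution at one site to an allele symbol.

    Returns the counted allele, or ``None`` for an excluded sample-site.
    """
    if base in VALID_BASES:
        return base
    if base == "N":
        return None
    if base == "-":
        # masked homopolymer deletion counts as reference; otherwise a gap allele
        return ref if deletion_masked else "-"
    if base in IUPAC2:
        if cfg.heteroplasmy_policy == "exclude_site_sample":
            return None
        if cfg.heteroplasmy_policy == "count_major":
            # the consensus code does not say which component dominated; count
            # the reference base when it is one of the two, else the
            # alphabetically first component (documented convention)
            return ref if ref in IUPAC2[base] else min(IUPAC2[base])
        return base  # iupac policy
    raise AlphabetError(f"invalid character {base!r}")


def build_site_counts(
    seqs: Sequence[MitoSequence],
    reference: str,
    cfg: CohortConfig | None = None,
) -> list[SiteCounts]:
    """Build one :class:`SiteCounts` per reference position.

    Heteroplasmic sample-sites are handled per ``cfg.heteroplasmy_policy``
    (default: excluded).  Positions where a sample has ``N`` contribute no
    count for that sample.  Indels masked by the homopolymer rule are
    treated as reference.  The major allele is the pooled argmax with
    alphabetical tie-break.

    The counting is vectorized over the sample x position character matrix;
    :func:`_column_symbol` documents the per-cell resolution rule it
    implements.
    """
    cfg = cfg or CohortConfig()
    groups = sorted({s.group for s in seqs})
    if len(groups) < 2:
        raise DegenerateCohortError(f"need >=2 groups, got {groups}")

    L = len(reference)
    for s in seqs:
        if len(s.bases) != L:
            raise AlignmentError(
                f"sample {s.sample_id!r} length {len(s.bases)} != reference {L}"
            )
    mat = np.frombuffer(
        "".join(s.bases for s in seqs).encode("ascii"), dtype=np.uint8
    ).reshape(len(seqs), L).copy()
    ref_arr = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    bad = set(np.unique(mat).tobytes().decode("ascii")) - VALID_CHARS
    if bad:
        raise AlphabetError(f"cohort contains invalid characters: {sorted(bad)}")

    # masked homopolymer deletion columns count as reference
    calls = mask_homopolymer_indels(calls_from_alignment(seqs, reference), reference, cfg)
    row_of = {s.sample_id: i for i, s in enumerate(seqs)}
    for call in calls:
        if call.masked and call.kind == "deletion":
            cols = np.arange(call.position - 1, call.position - 1 + len(call.ref_allele))
            mat[row_of[call.sample_id], cols] = ref_arr[cols]

    # resolve heteroplasmic (two-base IUPAC) cells per policy; "iupac" keeps
    # the code as its own allele
    if cfg.heteroplasmy_policy == "exclude_site_sample":
        for code in IUPAC2:
            mat[mat == ord(code)] = ord("N")  # excluded, same as missing
    elif cfg.heteroplasmy_policy == "count_major":
        # reference base when it is a component, else the alphabetically
        # first component (documented convention)
        for code, pair in IUPAC2.items():
            rows, cols = np.nonzero(mat == ord(code))
            for r, c in zip(rows, cols):
                ref_b = chr(ref_arr[c])
                mat[r, c] = ord(ref_b if ref_b in pair else min(pair))

    group_rows = {g: np.array([i for i, s in enumerate(seqs) if s.group == g]) for g in groups}
    symbols = sorted(set(np.unique(mat).tobytes().decode("ascii")) - {"N"})
    per_group = {
        g: np.stack([(mat[rows] == ord(sym)).sum(axis=0) for sym in symbols])
        for g, rows in group_rows.items()
    }  # each: (n_symbols, L)
    pooled = sum(per_group.values())
    totals = {g: per_group[g].sum(axis=0) for g in groups}
    empty = [g for g in groups if totals[g].max(initial=0) == 0]
    if empty:
        raise DegenerateCohortError(f"groups with zero countable samples everywhere: {empty}")

    # symbols sorted ascending, so argmax's first-max IS the alphabetical tie-break
    major_idx = np.argmax(pooled, axis=0)
    poly = (pooled >= 1).sum(axis=0) >= 2

    sites: list[SiteCounts] = []
    for j in range(L):
        counts = {
            g: {
                symbols[k]: int(per_group[g][k, j])
                for k in range(len(symbols))
                if per_group[g][k, j] > 0
            }
            for g in groups
        }
        major = symbols[major_idx[j]] if pooled[:, j].sum() > 0 else reference[j]
        sites.append(
            SiteCounts(
                position=j + 1,
                major_allele=major,
                counts_by_group=counts,
                polymorphic=bool(poly[j]),
            )
        )
    return sites


def build_site_counts_from_calls(
    calls: Sequence[VariantCall],
    metadata: Mapping[str, str],
    reference: str,
    cfg: CohortConfig | None = None,
) -> list[SiteCounts]:
    """Count-matrix entry point for the VCF path.

    Samples are assumed reference wherever they carry no call; sequences are
    reconstructed and routed through :func:`build_site_counts` so both entry
    points share one counting policy.
    """
    cfg = cfg or CohortConfig()
    seqs = rebuild_sequences(calls, metadata, reference)
    return build_site_counts(seqs, reference, cfg)


def rebuild_sequences(
    calls: Sequence[VariantCall],
    metadata: Mapping[str, str],
    reference: str,
) -> list[MitoSequence]:
    """Reconstruct aligned consensus sequences from SNP/deletion calls.

    Inverse of :func:`calls_from_alignment` for the call kinds it emits
    (insertions cannot be represented in the fixed-length alignment and are
    ignored with a warning).
    """
    arr: dict[str, list[str]] = {s: list(reference) for s in metadata}
    het: dict[str, dict[int, set[str]]] = {s: {} for s in metadata}
    for call in calls:
        if call.sample_id not in arr:
            raise MetadataError(f"sample {call.sample_id!r} absent from metadata")
        if call.kind == "insertion":
            warnings.warn(
                f"insertion at {call.position} cannot be represented in the "
                "fixed-length alignment; ignored"
            )
            continue
        if call.kind == "deletion":
            for p in range(call.position, call.position + len(call.ref_allele)):
                arr[call.sample_id][p - 1] = "-"
        elif call.heteroplasmic:
            pos_sets = het[call.sample_id].setdefault(
                call.position, {reference[call.position - 1]}
            )
            pos_sets.add(call.alt_allele)
        else:
            arr[call.sample_id][call.position - 1] = call.alt_allele
    for sample, positions in het.items():
        for pos, alleles in positions.items():
            if len(alleles) == 2:
                arr[sample][pos - 1] = IUPAC2_REV[frozenset(alleles)]
            else:
                arr[sample][pos - 1] = "N"  # >2 co-called bases: ambiguous
    return [
        MitoSequence(sample_id=s, bases="".join(arr[s]), group=metadata[s])
        for s in metadata
    ]
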