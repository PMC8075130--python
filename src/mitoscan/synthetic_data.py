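"""Synthetic mitogenome cohort generator with a machine-readable truth file.

Emulates the statistical structure the case-control scan assumes: a rooted
haplogroup tree whose founders carry cumulative defining variants, two
groups of unequal size (29 vs 59 by default), planted sites with
group-differential allele frequencies, sample-private mutations,
heteroplasmic positions (two-base IUPAC consensus codes), and deletions in
homopolymeric reference runs.  A single seeded generator drives every draw
in a fixed order, so one seed yields byte-identical cohorts.

The generator does not attempt coalescent realism: no recombination (true
of mtDNA), no along-genome mutation-rate heterogeneity, no selection.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .haplogroup_classify import HaplogroupDef, HaplogroupTree
from .io_and_matrix import IUPAC2_REV, MitoSequence, calls_from_alignment

logger = logging.getLogger("mitoscan")

BASES = np.array(list("ACGT"))

# fixed 23-entry topology (root + 22 named haplogroups) following standard
# mtDNA macro-structure: African L branches, M/N out of L3, R under N
_TOPOLOGY: list[tuple[str, str | None]] = [
    ("MRCA", None),
    ("L0", "MRCA"), ("L1", "MRCA"), ("L2", "MRCA"), ("L3", "MRCA"),
    ("M", "L3"), ("N", "L3"), ("R", "N"),
    ("H", "R"), ("U", "R"), ("J", "R"), ("T", "R"), ("V", "R"),
    ("K", "U"),
    ("L0a", "L0"), ("L1b", "L1"), ("L1c", "L1"), ("L2a", "L2"), ("L3e", "L3"),
    ("H1", "H"), ("H2", "H"), ("U5", "U"), ("M1", "M"),
]


@dataclass
class PlantedSite:
    """One site with group-specific derived-allele frequencies."""

    position: int
    derived_allele: str
    p_by_group: dict[str, float]


@dataclass
class SimConfig:
    """Cohort-simulation parameters.

    Defaults mirror the study conditions the pipeline targets: a 16,569-bp
    genome, groups of 29 (F) and 59 (NF), 22 haplogroups with a shared
    between-group distribution (near-zero haplogroup FST), and one planted
    site whose derived-allele frequencies reproduce the reconstructed
    4/29 vs 24/59 carrier table.  ``private_mutation_rate`` is a Poisson
    mean per sample chosen so the cohort yields on the order of the study's
    ~745 polymorphic sites.
    """

    genome_length: int = 16_569
    n_group: dict[str, int] = field(default_factory=lambda: {"F": 29, "NF": 59})
    n_haplogroups: int = 22
    variants_per_edge: int = 3
    group_haplogroup_probs: dict[str, list[float]] | None = None
    planted_sites: list[PlantedSite] = field(
        default_factory=lambda: [
            PlantedSite(11914, "A", {"F": 4 / 29, "NF": 24 / 59})
        ]
    )
    private_mutation_rate: float = 8.0
    heteroplasmy_rate: float = 0.05
    homopolymer_indel_rate: float = 0.05
    homopolymer_min_run: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        positions = [p.position for p in self.planted_sites]
        if len(set(positions)) != len(positions):
            raise ValueError("planted positions collide")
        for p in self.planted_sites:
            if not 1 <= p.position <= self.genome_length:
                raise ValueError(f"planted position {p.position} outside genome")
            for g, freq in p.p_by_group.items():
                if not 0.0 <= freq <= 1.0:
                    raise ValueError(f"planted frequency {freq} for group {g}")
        if self.group_haplogroup_probs is not None:
            for g, vec in self.group_haplogroup_probs.items():
                if abs(sum(vec) - 1.0) > 1e-9:
                    raise ValueError(f"probabilities for group {g} do not sum to 1")


@dataclass
class SyntheticTruth:
    """Everything the generator decided, for downstream recovery tests."""

    seed: int
    reference: str
    haplogroup_by_sample: dict[str, str]
    tree_defs: list[dict]
    planted: list[dict]  # position, derived_allele, p_by_group, realized per-group carrier counts
    heteroplasmies: list[dict]  # sample_id, position, alleles
    homopolymer_indels: list[dict]  # sample_id, position
    group_sizes: dict[str, int]

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=1, sort_keys=True)


def build_haplogroup_tree(
    rng: np.random.Generator,
    reference: str,
    n_haplogroups: int = 22,
    variants_per_edge: int = 3,
    forbidden: set[int] | None = None,
) -> HaplogroupTree:
    """Assign ``variants_per_edge`` random defining variants to each edge of
    the fixed topology (first ``n_haplogroups`` named nodes)."""
    if not 1 <= n_haplogroups <= len(_TOPOLOGY) - 1:
        raise ValueError(f"n_haplogroups must be in 1..{len(_TOPOLOGY) - 1}")
    forbidden = set(forbidden or ())
    L = len(reference)
    available = np.array(
        [p for p in range(1, L + 1) if p not in forbidden]
    )
    keep = {name for name, _ in _TOPOLOGY[: n_haplogroups + 1]}
    defs: list[HaplogroupDef] = []
    used: set[int] = set()
    for name, parent in _TOPOLOGY[: n_haplogroups + 1]:
        if parent is not None and parent not in keep:
            parent = "MRCA"  # reattach if the listed parent was trimmed
        if parent is None:
            defs.append(HaplogroupDef(name, None, frozenset()))
            continue
        variants: set[tuple[int, str]] = set()
        while len(variants) < variants_per_edge:
            pos = int(rng.choice(available))
            if pos in used:
                continue
            used.add(pos)
            ref_base = reference[pos - 1]
            derived = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            variants.add((pos, derived))
        defs.append(HaplogroupDef(name, parent, frozenset(variants)))
    return HaplogroupTree(defs)


def _reference_runs(reference: str, min_run: int) -> list[tuple[int, int]]:
    """(start, end) 1-based inclusive for single-base runs of length >= min_run."""
    runs = []
    i = 0
    L = len(reference)
    while i < L:
        j = i
        while j + 1 < L and reference[j + 1] == reference[i]:
            j += 1
        if j - i + 1 >= min_run:
            runs.append((i + 1, j + 1))
        i = j + 1
    return runs


def generate_cohort(
    cfg: SimConfig | None = None,
) -> tuple[str, list[MitoSequence], SyntheticTruth, HaplogroupTree]:
    """Draw a full cohort: reference, aligned sequences, truth, tree.

    Draw order (fixed for reproducibility): reference bases; defining
    variants per tree edge; per-sample haplogroup, planted alleles, private
    mutations; heteroplasmies; homopolymer deletions.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.genome_length

    ref_arr = rng.choice(BASES, size=L)
    # guarantee at least one homopolymeric block for the indel channel
    hp_start = min(303, max(1, L - 8))
    hp_len = min(7, L - hp_start + 1)
    ref_arr[hp_start - 1 : hp_start - 1 + hp_len] = "C"
    # planted sites sit on a fixed ancestral base distinct from the derived one
    for site in cfg.planted_sites:
        ref_arr[site.position - 1] = "G" if site.derived_allele != "G" else "A"
    reference = "".join(ref_arr)

    forbidden = {p.position for p in cfg.planted_sites}
    forbidden.update(range(hp_start, hp_start + hp_len))
    tree = build_haplogroup_tree(
        rng, reference, cfg.n_haplogroups, cfg.variants_per_edge, forbidden
    )
    node_names = sorted(n for n in tree.nodes if n != tree.root)

    if cfg.group_haplogroup_probs is None:
        # shared, even mixture: both groups draw haplogroups uniformly, so
        # between-group FST is ~0 and most haplogroups appear in a cohort of
        # ~88 (the heavily admixed regime the defaults emulate)
        shared = np.full(len(node_names), 1.0 / len(node_names))
        probs = {g: shared for g in cfg.n_group}
    else:
        probs = {
            g: np.asarray(cfg.group_haplogroup_probs[g]) for g in cfg.n_group
        }

    founders = {}
    for name in node_names:
        arr = ref_arr.copy()
        for pos, allele in tree.path_variants(name):
            arr[pos - 1] = allele
        founders[name] = arr

    sequences: list[MitoSequence] = []
    haplogroup_by_sample: dict[str, str] = {}
    realized = {
        site.position: {g: 0 for g in cfg.n_group} for site in cfg.planted_sites
    }
    planted_positions = {p.position for p in cfg.planted_sites}
    drawable = np.array([p for p in range(1, L + 1) if p not in planted_positions])

    for group in sorted(cfg.n_group):
        for k in range(cfg.n_group[group]):
            sid = f"{group}{k + 1:03d}"
            hg = str(rng.choice(node_names, p=probs[group]))
            haplogroup_by_sample[sid] = hg
            arr = founders[hg].copy()
            for site in cfg.planted_sites:
                if rng.random() < site.p_by_group.get(group, 0.0):
                    arr[site.position - 1] = site.derived_allele
                    realized[site.position][group] += 1
            n_priv = int(rng.poisson(cfg.private_mutation_rate))
            if n_priv:
                for pos in rng.choice(drawable, size=n_priv, replace=False):
                    cur = arr[pos - 1]
                    arr[pos - 1] = str(rng.choice([b for b in "ACGT" if b != cur]))
            sequences.append(
                MitoSequence(sample_id=sid, bases="".join(arr), group=group)
            )

    heteroplasmies: list[dict] = []
    for seq in sequences:
        if rng.random() < cfg.heteroplasmy_rate:
            pos = int(rng.choice(drawable))
            arr = list(seq.bases)
            cur = arr[pos - 1]
            other = str(rng.choice([b for b in "ACGT" if b != cur]))
            arr[pos - 1] = IUPAC2_REV[frozenset({cur, other})]
            seq.bases = "".join(arr)
            heteroplasmies.append(
                {"sample_id": seq.sample_id, "position": pos,
                 "alleles": "".join(sorted({cur, other}))}
            )

    runs = _reference_runs(reference, cfg.homopolymer_min_run)
    indels: list[dict] = []
    for seq in sequences:
        if runs and rng.random() < cfg.homopolymer_indel_rate:
            start, end = runs[int(rng.integers(len(runs)))]
            pos = int(rng.integers(start, end + 1))
            arr = list(seq.bases)
            arr[pos - 1] = "-"
            seq.bases = "".join(arr)
            indels.append({"sample_id": seq.sample_id, "position": pos})

    truth = SyntheticTruth(
        seed=cfg.seed,
        reference=reference,
        haplogroup_by_sample=haplogroup_by_sample,
        tree_defs=[
            {
                "name": d.name,
                "parent": d.parent,
                "variants": sorted(f"{p}{a}" for p, a in d.defining_variants),
            }
            for d in tree.nodes.values()
        ],
        planted=[
            {
                "position": s.position,
                "derived_allele": s.derived_allele,
                "p_by_group": s.p_by_group,
                "realized_carriers": realized[s.position],
            }
            for s in cfg.planted_sites
        ],
        heteroplasmies=heteroplasmies,
        homopolymer_indels=indels,
        group_sizes=dict(cfg.n_group),
    )
    logger.info(
        "generated cohort: %d samples, genome %d bp, %d haplogroups, seed %d",
        len(sequences), L, len(node_names), cfg.seed,
    )
    return reference, sequences, truth, tree


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_vcf(path: Path, reference: str, sequences: list[MitoSequence]) -> None:
    """Emit per-sample calls as a minimal single-contig VCF v4.2.

    SNPs use haploid GT (``1``); heteroplasmic sites use ``0/1`` with the
    per-sample AF field; aligned deletions are left-anchored indel records.
    """
    calls = calls_from_alignment(sequences, reference)
    samples = [s.sample_id for s in sequences]
    col = {sid: i for i, sid in enumerate(samples)}
    # site key -> (ref, {alt: index}), genotypes per sample
    sites: dict[int, dict] = {}
    for c in calls:
        if c.kind == "SNP":
            pos, ref, alt = c.position, c.ref_allele, c.alt_allele
        else:  # aligned deletion: anchor one base left
            if c.position == 1:
                continue  # unanchorable at origin in a linear VCF; skip
            pos = c.position - 1
            anchor = reference[pos - 1]
            ref = anchor + c.ref_allele
            alt = anchor
        rec = sites.setdefault(pos, {"ref": ref, "alts": [], "gt": {}})
        if len(rec["ref"]) < len(ref):  # widen REF for overlapping deletions
            rec["alts"] = [a + ref[len(rec["ref"]):] for a in rec["alts"]]
            rec["ref"] = ref
        elif len(ref) < len(rec["ref"]):
            alt = alt + rec["ref"][len(ref):]
        if alt not in rec["alts"]:
            rec["alts"].append(alt)
        ai = rec["alts"].index(alt) + 1
        rec["gt"][c.sample_id] = (ai, c.heteroplasmic)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chrM,length={len(reference)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos in sorted(sites):
            rec = sites[pos]
            cells = []
            for sid in samples:
                if sid in rec["gt"]:
                    ai, het = rec["gt"][sid]
                    cells.append(f"0/{ai}:0.5" if het else f"{ai}:1.0")
                else:
                    cells.append("0:.")
            fh.write(
                f"chrM\t{pos}\t.\t{rec['ref']}\t{','.join(rec['alts'])}\t.\tPASS\t.\tGT:AF\t"
                + "\t".join(cells) + "\n"
            )


def write_cohort_files(
    reference: str,
    sequences: list[MitoSequence],
    truth: SyntheticTruth,
    tree: HaplogroupTree,
    outdir,
) -> dict[str, Path]:
    """Write reference/cohort FASTA, VCF, metadata TSV, haplogroup-definition
    TSV and the truth JSON; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "reference": outdir / "reference.fasta",
        "cohort": outdir / "cohort.fasta",
        "vcf": outdir / "cohort.vcf",
        "metadata": outdir / "metadata.tsv",
        "haplogroups": outdir / "haplogroups.tsv",
        "lineage_map": outdir / "lineage_map.tsv",
        "truth": outdir / "truth.json",
    }
    _write_fasta(files["reference"], [("chrM", reference)])
    _write_fasta(files["cohort"], [(s.sample_id, s.bases) for s in sequences])
    write_vcf(files["vcf"], reference, sequences)
    with open(files["metadata"], "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s in sequences:
            fh.write(f"{s.sample_id}\t{s.group}\n")
    with open(files["haplogroups"], "w") as fh:
        fh.write("name\tparent\tvariants\n")
        for d in tree.nodes.values():
            variants = ",".join(sorted(f"{p}{a}" for p, a in d.defining_variants))
            fh.write(f"{d.name}\t{d.parent or '-'}\t{variants}\n")
    import importlib.resources as ir

    files["lineage_map"].write_text(
        (ir.files("mitoscan") / "data" / "lineage_map.tsv").read_text()
    )
    files["truth"].write_text(truth.to_json())
    return files
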