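"""Synthetic genomes and codon alignments with known planted truth.

Every downstream stage is testable without any external download: the
generator plants grammar-conformant WRKY domains of each group/subgroup,
pseudogene lesions, tandem/segmental duplicate pairs, 200-kb gene clusters
and R-/V-type introns, and records every planted label in a truth table.

The subgroup templates below are synthetic reference domains designed for
this generator: each subgroup gets a distinct linker/spacer vocabulary and
the zinc-finger spacing class observed for that subgroup, so
nearest-reference assignment has a well-separated target.  They are not
natural sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import UNPLACED, GeneRecord
from .selection import CODONS, CODON_AA, CodonAlignment, _EigenCache, gy94_Q
from .sequence_io import write_fasta, write_gff3
from .tree import TreeNode

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_BG_ALPHABET = "ADEFGIKLMNPQSTVY"        # backgrounds avoid W/C/H/R ambiguity
_MUT_ALPHABET = "ADEFGIKLMNPQSTVY"

_AA_TO_CODONS: dict[str, list[str]] = {}
for codon in CODONS:
    _AA_TO_CODONS.setdefault(CODON_AA[codon], []).append(codon)


def _domain(hepta: str, linker: str, sp1: str, sp2: str, tail: str) -> str:
    """Assemble heptapeptide + linker + zinc finger (C..C..H..H/C)."""
    return hepta + linker + "C" + sp1 + "C" + sp2 + "H" + tail


# Spacer strings use only letters that can never satisfy a C/H/W position.
# C2H2 spacings: first gap 4-5, second 22-23; C2HC: 7 and 26.  The residue
# six positions after the second C is fixed to V (the V-type intron anchor);
# each linker fixes an R (the R-type anchor) between heptapeptide and finger.

SUBGROUP_TEMPLATES: dict[str, str] = {
    "IIa": _domain("WRKYGQK", "TVRDSPLTDG", "DGYQT", "QIDSGVTLMNPEKAFDSTGLQI", "TH"),
    "IIb": _domain("WRKYGQK", "MARSEFTGDL", "PVSNM", "ETKNAVGSDLPFQIMTNEKGSAD", "SH"),
    "IIc": _domain("WRKYGQK", "EVRGSNFADT", "NSVAE", "LMFDSVKAGTQENPILSDFMTKQ", "AH"),
    "IId": _domain("WRKYGQK", "GLRTDAPMSE", "FTQIG", "NPQGAVDFSLITEKMQGANPDSF", "GH"),
    "IIe": _domain("WRKYGQK", "SIRAENTGPF", "DMLS", "SDKTFVQGAMLENIPSTDKFQGA", "LH"),
    "IIx": _domain("WKKYGQK", "QDRFGSLTNA", "EPTA", "AGFMDVSQTLENIKPADGSFTQ", "MH"),
}

# group I: two domains; the N-terminal one carries the WKKY variant.
GROUP_I_N_DOMAIN = _domain("WKKYGQK", "ADRSGQLTEF", "MTDS", "FLPQAVGENTSDIKAMFGQLST", "EH")
GROUP_I_C_DOMAIN = _domain("WRKYGQK", "FGRENDATSL", "QAPDM", "TDSFGVLENQIKAPMTSDGFLQA", "DH")

# group III: C2HC finger (CX7 C X26 H X C)
GROUP_III_DOMAIN = (
    "WRKYGQK" + "PLRGTDSEAF" + "C" + "GDTSNAQ" + "C"
    + "TVAFDGLMEKQSPINTDAGSFLQEMK" + "H" + "S" + "C"
)

DEFAULT_SUBGROUP_REFERENCES: list[tuple[str, str, str]] = [
    (f"ref_{sg}", sg, seq) for sg, seq in SUBGROUP_TEMPLATES.items()
]

# per-subgroup conserved-intron plan: R-type introns sit before the finger
# in most single-domain subgroups; IIa/IIb carry V-type introns inside the
# finger; the IIx-like (and group-I N) domains are intron-free.
DEFAULT_INTRON_PLAN: dict[str, Optional[str]] = {
    "I": "R", "IIa": "V", "IIb": "V", "IIc": "R", "IId": "R",
    "IIe": "R", "IIx": None, "III": "R",
}

DEFAULT_GROUP_COUNTS: dict[str, int] = {
    "I": 12, "IIa": 5, "IIb": 8, "IIc": 13, "IId": 5, "IIe": 9,
    "IIx": 2, "III": 7,
}

# pseudogene lesions per subgroup: mirrors the reported family breakdown
# (3 in I, 2 in IIa, 2 in IIc, 1 each in IIx and IIe = 9 total)
DEFAULT_PSEUDOGENE_PLAN: dict[str, int] = {
    "I": 3, "IIa": 2, "IIc": 2, "IIx": 1, "IIe": 1,
}


@dataclass
class DuplicatePlan:
    subgroup: str = "IIc"
    identity: float = 0.9
    chromosome_a: str = "4"
    chromosome_b: str = "4"


@dataclass
class ClusterPlan:
    chromosome: str
    positions: list[int]


@dataclass
class SynthConfig:
    group_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUNTS)
    )
    n_defective: int = 10
    pseudogene_plan: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PSEUDOGENE_PLAN)
    )
    frameshift_fraction: float = 0.3         # of pseudogenes; rest premature stop
    duplicate_pairs: list[DuplicatePlan] = field(
        default_factory=lambda: [DuplicatePlan()]
    )
    clusters: list[ClusterPlan] = field(
        default_factory=lambda: [
            ClusterPlan("1", [200_000, 280_000]),
            ClusterPlan("5", [150_000, 230_000]),
        ]
    )
    intron_plan: dict[str, Optional[str]] = field(
        default_factory=lambda: dict(DEFAULT_INTRON_PLAN)
    )
    intron_length_range: tuple[int, int] = (400, 800)
    domain_mutation_rate: float = 0.04
    background_length: tuple[int, int] = (60, 140)
    gene_spacing_bp: int = 250_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.group_counts.values()):
            raise ValueError("group counts must be >= 0")
        for plan in self.duplicate_pairs:
            if not 0 < plan.identity <= 1:
                raise ValueError("duplicate target identity must be in (0, 1]")


@dataclass
class SyntheticGenome:
    records: list[GeneRecord]
    truth: pd.DataFrame
    chromosomes: dict[str, str]

    def write(self, outdir, write_genome: bool = True) -> dict[str, Path]:
        """Write protein/CDS FASTA, GFF3, truth TSV (and genome FASTA)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "proteins.faa",
            "cds": outdir / "cds.fna",
            "gff": outdir / "genes.gff3",
            "truth": outdir / "truth.tsv",
        }
        write_fasta([(r.gene_id, r.protein) for r in self.records], paths["proteins"])
        write_fasta([(r.gene_id, r.cds) for r in self.records], paths["cds"])
        write_gff3([r for r in self.records if r.placed], paths["gff"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        if write_genome:
            paths["genome"] = outdir / "genome.fna"
            write_fasta(
                [(f"chr{c}", seq) for c, seq in sorted(self.chromosomes.items())],
                paths["genome"],
            )
        return paths


# ---------------------------------------------------------------------------
# gene construction helpers

_HEPTA_CHECK = None


def _hepta_regex():
    global _HEPTA_CHECK
    if _HEPTA_CHECK is None:
        from .domain_scanner import HEPTA_RE
        _HEPTA_CHECK = HEPTA_RE
    return _HEPTA_CHECK


def _background(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BG_ALPHABET), size=length))


def _mutate_domain(rng: np.random.Generator, domain: str, rate: float) -> str:
    """Point-substitute spacer/linker residues, preserving grammar anchors
    (heptapeptide, zinc-chelating residues, and the R/V intron anchors)."""
    fixed = set(range(7))                            # heptapeptide
    for i, ch in enumerate(domain):
        if ch in "CHWVR":
            fixed.add(i)
    out = list(domain)
    for i in range(len(out)):
        if i in fixed:
            continue
        if rng.random() < rate:
            out[i] = rng.choice(list(_MUT_ALPHABET))
    return "".join(out)


def _encode(rng: np.random.Generator, protein: str) -> str:
    return "".join(rng.choice(_AA_TO_CODONS[aa]) for aa in protein) + "TAA"


def _mutate_protein_to_identity(
    rng: np.random.Generator,
    protein: str,
    identity: float,
    domains: Sequence[tuple[int, str]] = (),
) -> str:
    """Substitute a fraction of background residues to hit a target identity.

    Positions inside a planted domain that anchor the grammar (the
    heptapeptide and any C/H/W/V/R residue) are never touched.
    """
    protected: set[int] = set()
    for start, dom in domains:
        protected.update(range(start, start + 7))
        for k, ch in enumerate(dom):
            if ch in "CHWVR":
                protected.add(start + k)
    n_mut = round(len(protein) * (1.0 - identity))
    mutable = [
        i for i, ch in enumerate(protein)
        if ch in _MUT_ALPHABET and i not in protected
    ]
    chosen = rng.choice(mutable, size=min(n_mut, len(mutable)), replace=False)
    out = list(protein)
    for i in chosen:
        alternatives = [c for c in _MUT_ALPHABET if c != out[i]]
        out[i] = rng.choice(alternatives)
    return "".join(out)


@dataclass
class _GeneSpec:
    gene_id: str
    group: str
    subgroup: Optional[str]
    pseudogene_kind: Optional[str] = None    # stop | frameshift | None
    duplicate_of: Optional[str] = None
    defective: bool = False


def _build_protein(
    rng: np.random.Generator, spec: _GeneSpec, cfg: SynthConfig
) -> tuple[str, list[tuple[int, str]]]:
    """Protein plus the list of (domain_start, domain_template) planted."""
    lo, hi = cfg.background_length
    bg_n = int(rng.integers(lo, hi + 1))
    bg_c = int(rng.integers(lo, hi + 1))
    rate = cfg.domain_mutation_rate
    if spec.defective:
        # heptapeptide with no finger: unclassifiable by construction
        stub = "WRKYGQK" + _background(rng, 20)
        protein = _background(rng, bg_n) + stub + _background(rng, bg_c)
        return protein, []
    if spec.group == "I":
        dom_n = _mutate_domain(rng, GROUP_I_N_DOMAIN, rate)
        dom_c = _mutate_domain(rng, GROUP_I_C_DOMAIN, rate)
        spacer = _background(rng, int(rng.integers(40, 80)))
        n_start = bg_n
        c_start = bg_n + len(dom_n) + len(spacer)
        protein = (
            _background(rng, bg_n) + dom_n + spacer + dom_c + _background(rng, bg_c)
        )
        return protein, [(n_start, dom_n), (c_start, dom_c)]
    if spec.group == "III":
        dom = _mutate_domain(rng, GROUP_III_DOMAIN, rate)
    else:
        dom = _mutate_domain(rng, SUBGROUP_TEMPLATES[spec.subgroup], rate)
    protein = _background(rng, bg_n) + dom + _background(rng, bg_c)
    return protein, [(bg_n, dom)]


def _intron_cut_point(
    protein: str, domain_start: int, domain: str, intron_type: str
) -> Optional[int]:
    """CDS nucleotide offset where the planted intron interrupts the CDS."""
    hepta_len = 7
    first_c = domain_start + domain.index("C", hepta_len)
    if intron_type == "R":
        # the template linker places an R between heptapeptide and finger
        for pos in range(domain_start + hepta_len, first_c):
            if protein[pos] == "R":
                return pos * 3 + 2                   # phase-2, splits the R codon
        return None
    if intron_type == "V":
        second_c = domain_start + domain.index("C", first_c - domain_start + 1)
        pos = second_c + 6
        return pos * 3                               # phase-0, before the V codon
    return None


def generate_genome(config: Optional[SynthConfig] = None) -> SyntheticGenome:
    """Generate a synthetic WRKY gene complement with full planted truth.

    Deterministic for a fixed ``config.seed``: the same config yields
    byte-identical FASTA/GFF3/TSV output.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    # ---- enumerate gene specs -------------------------------------------
    specs: list[_GeneSpec] = []
    counter = 0
    for group_key in ("I", "IIa", "IIb", "IIc", "IId", "IIe", "IIx", "III"):
        count = cfg.group_counts.get(group_key, 0)
        group = group_key if group_key in ("I", "III") else "II"
        subgroup = None if group_key in ("I", "III") else group_key
        n_pseudo = cfg.pseudogene_plan.get(group_key, 0)
        for k in range(count):
            counter += 1
            kind = None
            if k < n_pseudo:
                kind = (
                    "frameshift"
                    if k < round(n_pseudo * cfg.frameshift_fraction)
                    else "stop"
                )
            specs.append(
                _GeneSpec(f"synWRKY{counter:03d}", group, subgroup, kind)
            )
    for _ in range(cfg.n_defective):
        counter += 1
        specs.append(
            _GeneSpec(f"synWRKY{counter:03d}", "UNCLASSIFIED", None, defective=True)
        )

    # duplicate pairs: second member of each pair copies the first
    dup_plan_by_id: dict[str, DuplicatePlan] = {}
    claimed: set[str] = set()
    for plan in cfg.duplicate_pairs:
        members = [
            s for s in specs
            if s.subgroup == plan.subgroup and not s.pseudogene_kind
            and not s.defective and s.duplicate_of is None
            and s.gene_id not in claimed
        ]
        if len(members) < 2:
            raise ValueError(
                f"duplicate plan needs >= 2 clean {plan.subgroup} genes"
            )
        members[1].duplicate_of = members[0].gene_id
        dup_plan_by_id[members[1].gene_id] = plan
        claimed.update({members[0].gene_id, members[1].gene_id})

    # ---- sequences -------------------------------------------------------
    proteins: dict[str, str] = {}
    planted_domains: dict[str, list[tuple[int, str]]] = {}
    hepta_re = _hepta_regex()
    spec_by_id = {s.gene_id: s for s in specs}
    for spec in specs:
        if spec.duplicate_of:
            continue
        for _attempt in range(20):
            protein, doms = _build_protein(rng, spec, cfg)
            expected = len(doms) if not spec.defective else 1
            if len(hepta_re.findall(protein)) == expected:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError(f"could not build clean background for {spec.gene_id}")
        proteins[spec.gene_id] = protein
        planted_domains[spec.gene_id] = doms
    for spec in specs:
        if spec.duplicate_of is None:
            continue
        plan = dup_plan_by_id[spec.gene_id]
        proteins[spec.gene_id] = _mutate_protein_to_identity(
            rng, proteins[spec.duplicate_of], plan.identity,
            domains=planted_domains[spec.duplicate_of],
        )
        planted_domains[spec.gene_id] = planted_domains[spec.duplicate_of]

    # ---- placement -------------------------------------------------------
    chrom_cursor = {str(c): 100_000 for c in range(1, 7)}
    placements: dict[str, tuple[str, int]] = {}
    cluster_ids: dict[str, int] = {}
    placeable = [s for s in specs if not s.defective]
    queue = list(placeable)

    for dup in specs:
        if dup.duplicate_of is None:
            continue
        plan = dup_plan_by_id[dup.gene_id]
        src = spec_by_id[dup.duplicate_of]
        for spec, chrom in ((src, plan.chromosome_a), (dup, plan.chromosome_b)):
            if spec.gene_id in placements:
                continue
            placements[spec.gene_id] = (chrom, chrom_cursor[chrom])
            chrom_cursor[chrom] += cfg.gene_spacing_bp

    for cluster_index, plan in enumerate(cfg.clusters):
        base = chrom_cursor[plan.chromosome]
        for pos in plan.positions:
            spec = next(s for s in queue if s.gene_id not in placements)
            placements[spec.gene_id] = (plan.chromosome, base + pos)
            cluster_ids[spec.gene_id] = cluster_index
        chrom_cursor[plan.chromosome] = (
            base + max(plan.positions) + cfg.gene_spacing_bp
        )

    chrom_cycle = [str(c) for c in range(1, 7)]
    rri = 0
    for spec in queue:
        if spec.gene_id in placements:
            continue
        chrom = chrom_cycle[rri % 6]
        rri += 1
        placements[spec.gene_id] = (chrom, chrom_cursor[chrom])
        chrom_cursor[chrom] += cfg.gene_spacing_bp

    # ---- assemble records ------------------------------------------------
    records: list[GeneRecord] = []
    truth_rows = []
    gene_seqs: dict[str, tuple[str, int, str]] = {}   # chrom, pos, genomic seq
    for spec in specs:
        protein = proteins[spec.gene_id]
        cds = _encode(rng, protein)
        intron_types: list[str] = []
        exons = [(0, len(cds))]
        genomic = cds
        doms = planted_domains[spec.gene_id]
        itype = None
        if not spec.defective and doms:
            key = spec.subgroup or spec.group
            itype = cfg.intron_plan.get(key)
        if itype:
            dom_start, dom = doms[-1]                 # group I: C-terminal domain
            cut = _intron_cut_point(protein, dom_start, dom, itype)
            if cut is not None:
                ilen = int(rng.integers(*cfg.intron_length_range))
                intron = "GT" + "".join(rng.choice(list("ACGT"), size=ilen - 4)) + "AG"
                exons = [(0, cut), (cut + ilen, len(cds) + ilen)]
                genomic = cds[:cut] + intron + cds[cut:]
                intron_types.append(itype)
        if spec.pseudogene_kind == "stop":
            # overwrite a background codon upstream of the domain with TAA
            target = max(1, (doms[0][0] if doms else 5) - 3)
            cds = cds[: target * 3] + "TAA" + cds[target * 3 + 3:]
            genomic = genomic[: target * 3] + "TAA" + genomic[target * 3 + 3:]
        elif spec.pseudogene_kind == "frameshift":
            drop = 4                # delete one nt early in the first exon
            cds = cds[:drop] + cds[drop + 1:]
            genomic = genomic[:drop] + genomic[drop + 1:]
            exons = [(exons[0][0], exons[0][1] - 1)] + [
                (s - 1, e - 1) for s, e in exons[1:]
            ]
        chrom, pos = placements.get(spec.gene_id, (UNPLACED, None))
        rec = GeneRecord(
            gene_id=spec.gene_id,
            chromosome=chrom,
            start=(pos + 1) if pos is not None else None,
            protein=protein,
            cds=cds,
            exons=exons,
            strand="+",
            group_label=spec.group if not spec.defective else None,
            subgroup_label=spec.subgroup,
            pseudogene=spec.pseudogene_kind is not None,
        )
        records.append(rec)
        if pos is not None:
            gene_seqs[spec.gene_id] = (chrom, pos, genomic)
        truth_rows.append(
            {
                "gene_id": spec.gene_id,
                "group": spec.group,
                "subgroup": spec.subgroup or "",
                "chromosome": chrom,
                "position": (pos + 1) if pos is not None else "",
                "pseudogene": spec.pseudogene_kind or "",
                "duplicate_of": spec.duplicate_of or "",
                "intron_types": ",".join(intron_types),
                "defective": int(spec.defective),
                "cluster": cluster_ids.get(spec.gene_id, ""),
            }
        )

    # ---- chromosome sequences -------------------------------------------
    chromosomes: dict[str, str] = {}
    for chrom in sorted({c for c, _, _ in gene_seqs.values()}):
        genes = sorted(
            (pos, gid, seq) for gid, (c, pos, seq) in gene_seqs.items() if c == chrom
        )
        length = genes[-1][0] + len(genes[-1][2]) + 1_000
        arr = rng.choice(list("ACGT"), size=length)
        prev_end = 0
        for pos, gid, seq in genes:
            if pos < prev_end:
                raise ValueError(f"conflicting coordinates for {gid} on chr{chrom}")
            arr[pos:pos + len(seq)] = list(seq)
            prev_end = pos + len(seq)
        chromosomes[chrom] = "".join(arr)

    truth = pd.DataFrame(truth_rows)
    return SyntheticGenome(records=records, truth=truth, chromosomes=chromosomes)


# ---------------------------------------------------------------------------
# codon-alignment simulation

def simulate_codon_alignment(
    tree: TreeNode,
    kappa: float,
    omega_mixture: Sequence[tuple[float, float]],
    n_codons: int,
    seed: int = 0,
    codon_freqs: Optional[np.ndarray] = None,
) -> tuple[CodonAlignment, np.ndarray]:
    """Simulate codon evolution under GY94 along a tree.

    ``omega_mixture`` is a list of (weight, omega) site classes; each site
    draws a class, the root codon comes from the equilibrium distribution
    and each branch applies exp(Q_omega * t).  Returns the alignment and
    the per-site class indices (the planted truth).
    """
    rng = np.random.default_rng(seed)
    pi = (
        np.full(len(CODONS), 1.0 / len(CODONS))
        if codon_freqs is None
        else np.asarray(codon_freqs, dtype=float)
    )
    weights = np.array([w for w, _ in omega_mixture], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("omega mixture weights must sum to 1")
    omegas = [om for _, om in omega_mixture]
    site_class = rng.choice(len(omegas), size=n_codons, p=weights)
    cache = _EigenCache(pi)

    root_states = rng.choice(len(CODONS), size=n_codons, p=pi)
    leaf_states: dict[str, np.ndarray] = {}

    def evolve(parent_states: np.ndarray, node: TreeNode) -> None:
        for child in node.children:
            t = max(child.length or 0.0, 0.0)
            states = parent_states.copy()
            if t > 0:
                for k, om in enumerate(omegas):
                    mask = site_class == k
                    if not mask.any():
                        continue
                    P = cache.transition_matrix(kappa, om, t)
                    cum = P.cumsum(axis=1)
                    u = rng.random(mask.sum())
                    rows = cum[parent_states[mask]]
                    states[mask] = (u[:, None] > rows).sum(axis=1)
            if child.is_leaf:
                leaf_states[child.name] = states
            else:
                evolve(states, child)

    evolve(root_states, tree)
    taxa = tree.leaf_names()
    mat = np.vstack([leaf_states[t] for t in taxa])
    return CodonAlignment(taxa, mat), site_class
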