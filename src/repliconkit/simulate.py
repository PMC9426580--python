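"""Synthetic-data generators with the statistical structure the analysis
stages assume.

Each generator emulates one observable of a multipartite-genome study:

* codon-usage bias — every replicon draws per-amino-acid synonymous-codon
  frequencies from a symmetric Dirichlet(alpha); replicons sharing a
  ``bias_group`` (the chromosome and its chromids) share one draw, while
  xenologous plasmids draw independently.  Small alpha means strong bias.
* read depth — window depths are Poisson with mean
  ``depth_mean_per_copy * copy_number * prevalence``, so the expected
  replicon:chromosome depth ratio is (c*p) / (c_chr*p_chr).
* colony assays — Binomial(n, carriage probability).
* passaging — the deterministic loss/selection recursion of
  :func:`repliconkit.assays.project_prevalence` generation by generation,
  with a binomial bottleneck at each culture transfer.
* cross-strain differential expression — a shared regulon whose effects are
  bivariate-normal across two strains, with the within-regulon correlation
  chosen in closed form so the whole-table Pearson correlation has the
  requested expectation.
* Rep protein families — RepA and RepB evolve on one guide topology, RepC on
  the same topology with configured taxon swaps, reproducing the
  partitioning/replicase incongruence signature; each compatibility group
  carries a group-specific palindrome in its partitioning-site segment.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .assays import AssayCounts, prevalence_step
from .codon import FAMILIES
from .io import CDSRecord, DETable, Replicon, write_fasta, write_tsv

__all__ = [
    "RepliconSpec",
    "GenomeConfig",
    "DepthConfig",
    "ColonyConfig",
    "PassageConfig",
    "DEConfig",
    "RepFamilyConfig",
    "SimConfig",
    "simulate_replicon_set",
    "write_genome",
    "simulate_depth",
    "simulate_colony_assay",
    "simulate_passaging",
    "simulate_de_tables",
    "simulate_rep_families",
    "RepFamilySim",
]

_AAS = sorted(FAMILIES)  # 20 amino acids
_BASES = np.array(list("ACGT"))
_AA_LETTERS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class RepliconSpec:
    """One simulated replicon: codon-bias group plus depth parameters.

    ``copy_number`` may be fractional to emulate a population-averaged copy
    number; ``prevalence`` is the carrier fraction.
    """

    id: str
    role: str = "unknown"
    n_cds: int = 20
    cds_codons: int = 150
    copy_number: float = 1.0
    prevalence: float = 1.0
    bias_group: str | None = None  # defaults to own id (independent bias)

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError(f"{self.id}: prevalence must lie in [0,1]")
        if self.copy_number <= 0:
            raise ValueError(f"{self.id}: copy_number must be positive")

    @property
    def group(self) -> str:
        return self.bias_group or self.id


def _default_replicons() -> list[RepliconSpec]:
    # a desk-scale multipartite genome: one chromosome, two chromids sharing
    # its codon bias, four xenologous plasmids; depth parameters follow the
    # coverage pattern of the study system (one single-copy plasmid at 50%
    # prevalence, one elevated-copy plasmid, one near-duplicated chromid)
    return [
        RepliconSpec("chromosome", "chromosome", n_cds=60),
        RepliconSpec("chromid_153", "chromid", bias_group="chromosome", copy_number=1.9),
        RepliconSpec("chromid_72", "chromid", bias_group="chromosome"),
        RepliconSpec("plasmid_191", "plasmid"),
        RepliconSpec("plasmid_126", "plasmid"),
        RepliconSpec("plasmid_86", "plasmid", copy_number=1.3),
        RepliconSpec("plasmid_102", "plasmid", prevalence=0.5),
    ]


@dataclass
class GenomeConfig:
    replicons: list[RepliconSpec] = field(default_factory=_default_replicons)
    alpha: float = 0.5  # Dirichlet concentration; small = strong codon bias
    intergenic_bp: int = 20


@dataclass
class DepthConfig:
    depth_mean_per_copy: float = 100.0
    n_windows: int = 500
    window_bp: int = 1000


@dataclass
class ColonyConfig:
    n_tested: int = 70
    carriage_prob: float = 0.5


@dataclass
class PassageConfig:
    generations: int = 50
    loss_rate: float = 8e-5
    fitness_cost: float = 0.0
    p0: float = 1.0
    bottleneck_size: int = 1_000_000  # cells surviving each transfer
    transfer_interval: int = 25  # generations between transfers; 0 = none
    n_colonies: int = 450


@dataclass
class DEConfig:
    n_genes: int = 3668
    regulon_size: int = 809
    rho_target: float = 0.76
    effect_sd: float = 2.0
    null_sd: float = 0.5


@dataclass
class RepFamilyConfig:
    # two compatibility groups of four plasmids each by default
    groups: dict[str, list[str]] = field(
        default_factory=lambda: {
            "I": ["tA", "tB", "tC", "tD"],
            "II": ["tE", "tF", "tG", "tH"],
        }
    )
    # branch lengths chosen so between-group distances exceed within-group
    # ones by >= 3x, the separation under which grouping is well-posed
    within_branch: float = 0.03  # expected substitutions/site inside a group
    between_branch: float = 0.4  # branch separating groups
    seq_len: int = 300  # typical ParA-family partitioning-protein length
    repc_swaps: list[tuple[str, str]] = field(default_factory=list)
    palindrome_arm: int = 6
    palindrome_loop: int = 4
    palindrome_max_mut: int = 1
    flank_bp: int = 20


@dataclass
class SimConfig:
    """Bundle of all generator settings; the defaults are the study
    conditions every acceptance-level check runs under."""

    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    depth: DepthConfig = field(default_factory=DepthConfig)
    colony: ColonyConfig = field(default_factory=ColonyConfig)
    passage: PassageConfig = field(default_factory=PassageConfig)
    de: DEConfig = field(default_factory=DEConfig)
    rep_families: RepFamilyConfig = field(default_factory=RepFamilyConfig)


# ---------------------------------------------------------------------------
# replicon sequences with codon bias


def _bias_vectors(rng: np.random.Generator, alpha: float) -> dict[str, np.ndarray]:
    return {aa: rng.dirichlet([alpha] * len(FAMILIES[aa])) for aa in _AAS}


def _random_cds(rng: np.random.Generator, bias: dict[str, np.ndarray], n_codons: int) -> str:
    aas = rng.choice(_AAS, size=n_codons)
    codons = np.empty(n_codons, dtype=object)
    for aa in np.unique(aas):
        mask = aas == aa
        fam = FAMILIES[aa]
        codons[mask] = rng.choice(fam, size=int(mask.sum()), p=bias[aa])
    return "ATG" + "".join(codons) + "TAA"


def simulate_replicon_set(
    config: GenomeConfig, seed: int | None = None
) -> list[Replicon]:
    """Generate replicons whose CDSs follow per-bias-group codon usage."""
    if config.alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    bias_of: dict[str, dict[str, np.ndarray]] = {}
    for spec in config.replicons:
        if spec.group not in bias_of:
            bias_of[spec.group] = _bias_vectors(rng, config.alpha)
    replicons = []
    for spec in config.replicons:
        bias = bias_of[spec.group]
        parts: list[str] = []
        cds_list: list[CDSRecord] = []
        pos = 0
        for g in range(spec.n_cds):
            gap = "".join(rng.choice(_BASES, size=config.intergenic_bp))
            cds = _random_cds(rng, bias, spec.cds_codons)
            start = pos + len(gap)
            cds_list.append(
                CDSRecord(
                    gene_id=f"{spec.id}_g{g:04d}",
                    replicon_id=spec.id,
                    start=start,
                    end=start + len(cds),
                    strand="+",
                )
            )
            parts.append(gap + cds)
            pos = start + len(cds)
        seq = "".join(parts)
        replicons.append(
            Replicon(
                id=spec.id,
                length=len(seq),
                declared_role=spec.role,
                sequence=seq,
                cds_list=cds_list,
            )
        )
    return replicons


def write_genome(replicons: list[Replicon], fasta_path, cds_tsv_path) -> None:
    write_fasta(((r.id, r.sequence) for r in replicons), fasta_path)
    rows = [
        (c.gene_id, c.replicon_id, c.start, c.end, c.strand, c.phase)
        for r in replicons
        for c in r.cds_list
    ]
    write_tsv(
        pd.DataFrame(rows, columns=["gene_id", "replicon_id", "start", "end", "strand", "phase"]),
        cds_tsv_path,
    )


# ---------------------------------------------------------------------------
# depth


def simulate_depth(
    replicons: list[RepliconSpec], config: DepthConfig, seed: int | None = None
) -> pd.DataFrame:
    """Per-window mean depths, Poisson around depth_mean_per_copy * c * p."""
    if config.depth_mean_per_copy <= 0:
        raise ValueError("depth_mean_per_copy must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for spec in replicons:
        mean = config.depth_mean_per_copy * spec.copy_number * spec.prevalence
        depths = rng.poisson(mean, size=config.n_windows).astype(float)
        starts = np.arange(config.n_windows) * config.window_bp
        frames.append(
            pd.DataFrame(
                {
                    "replicon_id": spec.id,
                    "window_start": starts,
                    "window_end": starts + config.window_bp,
                    "depth": depths,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# colony assays and passaging


def simulate_colony_assay(n: int, carriage_prob: float, seed: int | None = None) -> AssayCounts:
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    k = int(rng.binomial(n, carriage_prob))
    return AssayCounts(n_tested=n, n_positive=k, label=f"simulated(p={carriage_prob})")


def simulate_passaging(
    config: PassageConfig, seed: int | None = None
) -> tuple[np.ndarray, AssayCounts]:
    """Carrier fraction over ``generations`` with transfer bottlenecks,
    followed by a colony screen of the final culture."""
    rng = np.random.default_rng(seed)
    traj = np.empty(config.generations + 1)
    p = config.p0
    traj[0] = p
    for t in range(1, config.generations + 1):
        p = prevalence_step(p, config.loss_rate, config.fitness_cost)
        if (
            config.transfer_interval > 0
            and t % config.transfer_interval == 0
            and t < config.generations
        ):
            p = rng.binomial(config.bottleneck_size, p) / config.bottleneck_size
        traj[t] = p
    assay = AssayCounts(
        n_tested=config.n_colonies,
        n_positive=int(rng.binomial(config.n_colonies, p)),
        label="passaged",
    )
    return traj, assay


# ---------------------------------------------------------------------------
# differential expression


def attainable_rho_max(config: DEConfig) -> float:
    """Largest whole-table correlation the mixture can reach (regulon
    perfectly correlated, null genes independent)."""
    f = config.regulon_size / config.n_genes
    ve, v0 = config.effect_sd**2, config.null_sd**2
    return f * ve / (f * ve + (1 - f) * v0)


def simulate_de_tables(config: DEConfig, seed: int | None = None) -> list[DETable]:
    """Two strains' log2 fold-change tables sharing a correlated regulon.

    Within the regulon, per-gene effects in the two strains are bivariate
    normal with correlation rho_w solved from
    rho_target = f * rho_w * sd_e^2 / (f * sd_e^2 + (1-f) * sd_0^2),
    so the whole-table Pearson correlation has expectation rho_target.
    Regulon genes receive small p-values (Beta(0.05, 1)); null genes uniform.
    """
    if not 0 <= config.rho_target <= 1:
        raise ValueError("rho_target must lie in [0, 1]")
    rho_max = attainable_rho_max(config)
    if config.rho_target > rho_max:
        raise ValueError(
            f"rho_target={config.rho_target} unattainable; with this regulon fraction "
            f"and SDs the attainable range is [0, {rho_max:.4f}]"
        )
    rng = np.random.default_rng(seed)
    m, n = config.regulon_size, config.n_genes
    f = m / n
    ve, v0 = config.effect_sd**2, config.null_sd**2
    rho_w = config.rho_target * (f * ve + (1 - f) * v0) / (f * ve) if m else 0.0

    cov = config.effect_sd**2 * np.array([[1.0, rho_w], [rho_w, 1.0]])
    eff = rng.multivariate_normal([0.0, 0.0], cov, size=m)
    null = rng.normal(0.0, config.null_sd, size=(n - m, 2))
    fc = np.vstack([eff, null])
    genes = [f"gene_{i:05d}" for i in range(n)]
    tables = []
    for j, strain in enumerate(("strainA", "strainB")):
        pvals = np.concatenate(
            [rng.beta(0.05, 1.0, size=m), rng.uniform(0.0, 1.0, size=n - m)]
        )
        df = pd.DataFrame(
            {
                "gene_id": genes,
                "replicon_id": "chromosome",
                "log2fc": fc[:, j],
                "pvalue": np.clip(pvals, 0.0, 1.0),
            }
        )
        tables.append(DETable(strain=strain, reference="reference", data=df))
    return tables


# ---------------------------------------------------------------------------
# Rep protein families


@dataclass
class RepFamilySim:
    families: dict[str, "object"]  # name -> ProteinFamily
    truth_ab: skbio.TreeNode
    truth_c: skbio.TreeNode
    palindrome_segments: dict[str, str]
    group_palindromes: dict[str, str]
    groups: dict[str, str]  # taxon -> group name


def _random_clade(rng: np.random.Generator, taxa: list[str], branch: float) -> skbio.TreeNode:
    nodes = [skbio.TreeNode(name=t, length=branch) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = skbio.TreeNode(length=branch)
        parent.extend([a, b])
        nodes.append(parent)
    return nodes[0]


def _evolve(
    rng: np.random.Generator, tree: skbio.TreeNode, root_seq: np.ndarray
) -> dict[str, str]:
    """Site-independent substitutions: Poisson(branch * L) positions mutate to
    a uniformly drawn different residue."""
    seqs: dict[str, str] = {}

    def recurse(node: skbio.TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            s = seq.copy()
            nsub = rng.poisson((child.length or 0.0) * len(s))
            for pos in rng.integers(0, len(s), size=nsub):
                choices = _AA_LETTERS[_AA_LETTERS != s[pos]]
                s[pos] = rng.choice(choices)
            if child.is_tip():
                seqs[child.name] = "".join(s)
            else:
                recurse(child, s)

    recurse(tree, root_seq)
    return seqs


def _swap_labels(tree: skbio.TreeNode, swaps: list[tuple[str, str]]) -> skbio.TreeNode:
    out = tree.copy()
    tips = {t.name: t for t in out.tips()}
    for x, y in swaps:
        if x not in tips or y not in tips:
            raise ValueError(f"swap pair ({x}, {y}) references unknown taxa")
        tips[x].name, tips[y].name = y, x
    return out


def simulate_rep_families(config: RepFamilyConfig, seed: int | None = None) -> RepFamilySim:
    """RepA/RepB/RepC families on congruent vs. swapped topologies plus
    group-specific palindrome-bearing DNA segments."""
    from .repabc import ProteinFamily  # deferred: avoid import cycle

    all_taxa = [t for taxa in config.groups.values() for t in taxa]
    if len(all_taxa) != len(set(all_taxa)):
        raise ValueError("taxa must be unique across groups")
    if len(all_taxa) < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)

    # guide topology: random binary clade per group, clades chained with long
    # between-group branches
    clades = [
        _random_clade(rng, config.groups[g], config.within_branch)
        for g in sorted(config.groups)
    ]
    root = clades[0]
    for clade in clades[1:]:
        new_root = skbio.TreeNode()
        root.length = config.between_branch / 2
        clade.length = config.between_branch / 2
        new_root.extend([root, clade])
        root = new_root
    guide = root
    repc_tree = _swap_labels(guide, config.repc_swaps)

    families = {}
    for name, tree in (("RepA", guide), ("RepB", guide), ("RepC", repc_tree)):
        root_seq = rng.choice(_AA_LETTERS, size=config.seq_len)
        families[name] = ProteinFamily(name=name, sequences=_evolve(rng, tree, root_seq), aligned=True)

    # group-specific palindromes embedded in partitioning-site segments
    group_pal: dict[str, str] = {}
    segments: dict[str, str] = {}
    groups_of: dict[str, str] = {}
    for gname in sorted(config.groups):
        arm = "".join(rng.choice(_BASES, size=config.palindrome_arm))
        loop = "".join(rng.choice(_BASES, size=config.palindrome_loop))
        from .assays import reverse_complement

        pal = arm + loop + reverse_complement(arm)
        group_pal[gname] = pal
        for taxon in config.groups[gname]:
            groups_of[taxon] = gname
            site = list(pal)
            nmut = int(rng.integers(0, config.palindrome_max_mut + 1))
            for pos in rng.choice(len(site), size=nmut, replace=False):
                site[pos] = str(rng.choice(_BASES[_BASES != site[pos]]))
            left = "".join(rng.choice(_BASES, size=config.flank_bp))
            right = "".join(rng.choice(_BASES, size=config.flank_bp))
            segments[taxon] = left + "".join(site) + right
    return RepFamilySim(
        families=families,
        truth_ab=guide,
        truth_c=repc_tree,
        palindrome_segments=segments,
        group_palindromes=group_pal,
        groups=groups_of,
    )
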