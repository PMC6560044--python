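"""Seeded generator of synthetic inputs with planted truth.

Emulates the data layout of a comparative study of duplicate genes encoding
one invariant protein: ortholog panels of equal-length CDSs that differ only
at synonymous sites, evolved along a star (or newick) species tree with
paralog-specific rates and codon-bias targets; transcriptional-program gene
sets whose codons are drawn from distinct target profiles; gene
neighborhoods with planted orthologs among unrelated decoys; and 3'UTRs
diverged by substitutions and indels.

The substitution process operates in codon space: an event resamples one
codon among its synonyms (optionally biased toward a target codon-usage
profile). This guarantees protein invariance by construction — the central
premise of the analysis — at the cost of not modelling
transition/transversion bias.

All randomness flows from a single integer seed; per-gene substreams are
derived deterministically, so outputs are byte-identical across runs and
independent of iteration order.
"""

from __future__ import annotations

import json
import zlib
from collections import Counter
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

from .codon_usage import CodonUsageProfile, aa_specific_frequencies, codon_counts
from .genetic_code import (
    AMINO_ACIDS,
    CODON_TO_AA,
    SENSE_CODONS,
    synonymous_codons,
    translate,
)
from .records import GeneRecord

__all__ = [
    "DEFAULT_PROTEIN",
    "SimulationConfig",
    "UtrParams",
    "NeighborhoodParams",
    "ProgramParams",
    "PlantedTruth",
    "replay_events",
    "random_utr",
    "uniform_profile",
    "random_profile",
    "profile_divergence",
    "sample_protein",
    "sample_gene",
    "evolve_synonymous",
    "simulate_family",
    "simulate_neighborhoods",
    "evolve_utr",
    "sample_program_gene_sets",
]

#: Fixed 136-residue protein of realistic vertebrate composition, matching
#: the length scale of a replication-independent H3 variant. Synthetic —
#: generated once from proteome-average amino-acid frequencies, not a
#: database sequence.
DEFAULT_PROTEIN = (
    "MLLALYGLTKASAKTRDHFKKRIDIPAFSAPGCNEVEDQQDKLYNLDTADSRSKTSCSSITKEAKEKIIM"
    "YVGQLIETMQQKLRNESDTSVEGPARQLCEFPFVSYTVLMFGAKQLIADERGRPGGLKFHLVYPTL"
)

#: Proteome-average amino-acid frequencies used to sample decoy proteins.
_AA_COMPOSITION = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.036, "G": 0.066,
    "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100, "M": 0.021, "N": 0.036,
    "P": 0.063, "Q": 0.048, "R": 0.056, "S": 0.083, "T": 0.053, "V": 0.060,
    "W": 0.012, "Y": 0.027,
}


def _rng(seed: int, *keys: object) -> np.random.Generator:
    """Deterministic substream: seed plus stable hashes of the keys."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class UtrParams:
    """3'UTR divergence model: per-site substitution rate, indel rate per
    site, geometric mean indel length, and the emitted UTR length."""

    sub_rate: float = 0.25
    indel_rate: float = 0.02
    mean_indel_len: float = 3.0
    length: int = 500


@dataclass
class NeighborhoodParams:
    """Planted-synteny layout: ortholog/decoy counts per side, decoy protein
    length, intergenic spacing, planted synonymous divergence (branch
    length per wobble site) and nonsynonymous substitution rate."""

    planted: int = 10
    decoys: int = 20
    decoy_protein_len: int = 100
    spacing_bp: int = 30_000
    ortholog_branch_length: float = 0.2
    nonsyn_rate: float = 0.05


@dataclass
class ProgramParams:
    """Program gene-set generation: genes per program, protein length, and
    Dirichlet concentration of the program codon-bias profiles (smaller =
    more divergent programs)."""

    n_genes: int = 200
    protein_len: int = 136
    concentration: float = 0.5


@dataclass
class SimulationConfig:
    """All knobs of the generator, with the study's default conditions.

    ``paralog_rates`` multiplies the tree's branch lengths per paralog: the
    default (A at rate 1, B at rate 5) plants a strongly conserved paralog
    against a faster-evolving one, the regime the conservation analysis is
    meant to detect. ``branch_length`` is in expected substitution events
    per wobble site; ``bias_strength`` in [0,1] mixes the target codon
    profile with uniform-over-synonyms resampling.
    """

    seed: int = 0
    protein: str = DEFAULT_PROTEIN
    n_tips: int = 8
    branch_length: float = 0.05
    newick: str | None = None
    paralog_rates: dict[str, float] = field(
        default_factory=lambda: {"A": 1.0, "B": 5.0}
    )
    target_profiles: dict[str, CodonUsageProfile] | None = None
    bias_strength: float = 0.0
    utr: UtrParams = field(default_factory=UtrParams)
    neighborhood: NeighborhoodParams = field(default_factory=NeighborhoodParams)
    program: ProgramParams = field(default_factory=ProgramParams)


@dataclass
class PlantedTruth:
    """Replayable record of what the generator did.

    ``family_profiles`` names the generating profile per paralog;
    ``branch_substitutions`` the realized substitution-event count per
    (paralog, tip); ``ortholog_pairs`` the planted query->reference gene id
    map for neighborhoods; ``utr_edits`` the per-UTR edit operations.
    """

    family_profiles: dict[str, str] = field(default_factory=dict)
    branch_substitutions: dict[str, int] = field(default_factory=dict)
    branch_events: dict[str, list] = field(default_factory=dict)
    ancestors: dict[str, str] = field(default_factory=dict)
    ortholog_pairs: dict[str, str] = field(default_factory=dict)
    utr_edits: dict[str, list] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


# ---------------------------------------------------------------------------
# profiles

def uniform_profile(source: str = "uniform") -> CodonUsageProfile:
    """aa_specific profile that is uniform over each amino acid's synonyms."""
    counts = {c: 1 for c in SENSE_CODONS}
    return aa_specific_frequencies(counts, source=source)


def random_profile(
    rng: np.random.Generator, concentration: float = 0.5, source: str = "random"
) -> CodonUsageProfile:
    """aa_specific profile with Dirichlet-sampled synonym preferences.

    Smaller ``concentration`` gives spikier (more biased) codon preferences
    and therefore larger divergence between independently drawn profiles.
    """
    freqs: dict[str, float] = {}
    counts: dict[str, int] = {}
    for aa in sorted(AMINO_ACIDS):
        syns = sorted(synonymous_codons(aa))
        probs = rng.dirichlet([concentration] * len(syns))
        for c, p in zip(syns, probs):
            freqs[c] = float(p)
            counts[c] = max(1, int(round(1000 * p)))
    return CodonUsageProfile("aa_specific", counts, freqs, source)


def profile_divergence(p_a: CodonUsageProfile, p_b: CodonUsageProfile) -> float:
    """Mean Jensen–Shannon divergence (base 2) between the per-amino-acid
    conditional codon distributions of two aa_specific profiles.

    Only amino acids with at least two codons and defined frequencies in
    both profiles contribute.
    """
    if p_a.metric != "aa_specific" or p_b.metric != "aa_specific":
        raise ValueError("profile_divergence requires aa_specific profiles")
    divs = []
    for aa in sorted(AMINO_ACIDS):
        syns = sorted(synonymous_codons(aa))
        if len(syns) < 2:
            continue
        if not all(c in p_a.frequencies and c in p_b.frequencies for c in syns):
            continue
        va = np.array([p_a.frequencies[c] for c in syns])
        vb = np.array([p_b.frequencies[c] for c in syns])
        divs.append(float(jensenshannon(va, vb, base=2) ** 2))
    if not divs:
        raise ValueError("no shared multi-codon amino acids")
    return float(np.mean(divs))


def _synonym_mixture(
    aa: str, profile: CodonUsageProfile | None, bias_strength: float
) -> tuple[list[str], np.ndarray]:
    syns = sorted(synonymous_codons(aa))
    uniform = np.full(len(syns), 1.0 / len(syns))
    if profile is None or bias_strength == 0.0:
        return syns, uniform
    missing = [c for c in syns if c not in profile.frequencies]
    if missing:
        raise ValueError(f"profile undefined for amino acid {aa!r}")
    target = np.array([profile.frequencies[c] for c in syns])
    total = target.sum()
    if total == 0:
        return syns, uniform
    target = target / total
    return syns, bias_strength * target + (1.0 - bias_strength) * uniform


# ---------------------------------------------------------------------------
# sampling and evolution

def sample_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein of proteome-average composition, starting with Met."""
    aas = sorted(_AA_COMPOSITION)
    p = np.array([_AA_COMPOSITION[a] for a in aas])
    p = p / p.sum()
    body = rng.choice(aas, size=length - 1, p=p)
    return "M" + "".join(body)


def sample_gene(
    protein: str,
    profile: CodonUsageProfile | None,
    bias_strength: float,
    rng: np.random.Generator,
) -> str:
    """Sample a CDS encoding ``protein`` exactly.

    Each codon is drawn from the mixture
    ``bias_strength * profile + (1 - bias_strength) * uniform-over-synonyms``.
    """
    codons = []
    for aa in protein:
        syns, probs = _synonym_mixture(aa, profile, bias_strength)
        codons.append(syns[rng.choice(len(syns), p=probs)])
    cds = "".join(codons)
    assert translate(cds) == protein
    return cds


def _wobble_codon_indices(cds: str) -> list[int]:
    """Indices of codons whose amino acid has at least two synonyms."""
    return [
        i
        for i in range(len(cds) // 3)
        if len(synonymous_codons(CODON_TO_AA[cds[3 * i : 3 * i + 3]])) > 1
    ]


def evolve_synonymous(
    cds: str,
    branch_length: float,
    target_profile: CodonUsageProfile | None = None,
    bias_strength: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[str, list[tuple[int, str]]]:
    """Evolve a CDS along one branch, changing synonymous sites only.

    The number of substitution events is Poisson with mean
    ``branch_length * (number of codons with >1 synonym)``; each event
    resamples one such codon among its synonyms from the biased mixture
    (an event may redraw the same codon — the process is Jukes-Cantor-like
    in codon space, so observed divergence saturates below the event
    count). Returns the evolved CDS and the event list as
    ``(codon_index, new_codon)`` pairs — replaying the events over the
    input reproduces the output exactly. The encoded protein is invariant
    by construction.
    """
    rng = rng if rng is not None else np.random.default_rng()
    protein = translate(cds)
    sites = _wobble_codon_indices(cds)
    if not sites or branch_length == 0:
        return cds, []
    n_events = int(rng.poisson(branch_length * len(sites)))
    codons = [cds[3 * i : 3 * i + 3] for i in range(len(cds) // 3)]
    events: list[tuple[int, str]] = []
    for _ in range(n_events):
        i = sites[rng.choice(len(sites))]
        aa = CODON_TO_AA[codons[i]]
        syns, probs = _synonym_mixture(aa, target_profile, bias_strength)
        codons[i] = syns[rng.choice(len(syns), p=probs)]
        events.append((i, codons[i]))
    out = "".join(codons)
    assert translate(out) == protein
    return out, events


def replay_events(cds: str, events: Sequence[Sequence]) -> str:
    """Apply recorded substitution events to a CDS (truth replay)."""
    codons = [cds[3 * i : 3 * i + 3] for i in range(len(cds) // 3)]
    for i, codon in events:
        codons[int(i)] = str(codon)
    return "".join(codons)


def _tip_branch_lengths(config: SimulationConfig) -> list[tuple[str, float]]:
    """Tip name -> root-to-tip branch length (star tree or newick)."""
    if config.newick is None:
        return [
            (f"sp{i + 1}", config.branch_length) for i in range(config.n_tips)
        ]
    import io as _io

    from Bio import Phylo

    tree = Phylo.read(_io.StringIO(config.newick), "newick")
    tips = []
    for leaf in tree.get_terminals():
        depth = tree.distance(tree.root, leaf)
        tips.append((leaf.name or f"tip{len(tips) + 1}", float(depth)))
    if not tips:
        raise ValueError("newick tree has no tips")
    return tips


def simulate_family(
    config: SimulationConfig,
) -> tuple[dict[str, list[tuple[str, str]]], PlantedTruth]:
    """Simulate ortholog panels for each paralog of one gene family.

    A single ancestral CDS is sampled for the config protein; for each
    paralog, every tree tip receives an independently evolved copy with the
    paralog's rate multiplier applied to the branch lengths and the
    paralog's target profile (if any) biasing the substitutions. Returns
    ``{paralog: [(tip_id, cds), ...]}`` plus the planted truth.

    Root-to-tip evolution is a single compound branch per tip (a star tree
    by default), which is what the conservation statistics assume: the
    tips are exchangeable within a paralog.
    """
    truth = PlantedTruth()
    rng_anc = _rng(config.seed, "family", "ancestor")
    ancestor = sample_gene(config.protein, None, 0.0, rng_anc)
    truth.ancestors["family"] = ancestor

    families: dict[str, list[tuple[str, str]]] = {}
    for paralog, rate in sorted(config.paralog_rates.items()):
        profile = (config.target_profiles or {}).get(paralog)
        truth.family_profiles[paralog] = profile.source if profile else "uniform"
        tips = []
        for tip_name, bl in _tip_branch_lengths(config):
            rng = _rng(config.seed, "family", paralog, tip_name)
            cds, events = evolve_synonymous(
                ancestor, bl * rate, profile, config.bias_strength, rng
            )
            tip_id = f"{paralog}_{tip_name}"
            tips.append((tip_id, cds))
            truth.branch_substitutions[tip_id] = len(events)
            truth.branch_events[tip_id] = [list(e) for e in events]
        families[paralog] = tips
    return families, truth


def _nonsyn_noise(
    cds: str, rate: float, rng: np.random.Generator
) -> str:
    """Substitute amino acids at the given per-residue rate (codon resampled
    uniformly among the new amino acid's synonyms). Position 0 (Met start)
    is left untouched."""
    if rate == 0:
        return cds
    codons = [cds[3 * i : 3 * i + 3] for i in range(len(cds) // 3)]
    aas = sorted(AMINO_ACIDS)
    for i in range(1, len(codons)):
        if rng.random() < rate:
            old = CODON_TO_AA[codons[i]]
            new = old
            while new == old:
                new = aas[rng.choice(len(aas))]
            syns = sorted(synonymous_codons(new))
            codons[i] = syns[rng.choice(len(syns))]
    return "".join(codons)


def simulate_neighborhoods(
    config: SimulationConfig,
) -> tuple[list[GeneRecord], list[GeneRecord], PlantedTruth]:
    """Two synthetic genomes: a focal gene, planted orthologs, and decoys.

    Genome A carries the focal gene flanked by ``planted`` orthologs and
    ``decoys`` unrelated genes, evenly spaced. Genome B carries an ortholog
    of the focal gene, orthologous copies of every planted gene (diverged
    by synonymous evolution at ``ortholog_branch_length`` plus
    nonsynonymous noise at ``nonsyn_rate``), and its own unrelated decoys.
    Truth records the planted ortholog pairing.
    """
    p = config.neighborhood
    truth = PlantedTruth()
    genomes: dict[str, list[GeneRecord]] = {"A": [], "B": []}

    # planted genes: sample in A, evolve into B
    planted_pairs: list[tuple[str, str, str, str]] = []  # idA, cdsA, idB, cdsB
    for k in range(p.planted):
        rng = _rng(config.seed, "nbhd", "planted", k)
        protein = sample_protein(rng, p.decoy_protein_len)
        cds_a = sample_gene(protein, None, 0.0, rng)
        cds_b, _ = evolve_synonymous(
            cds_a, p.ortholog_branch_length, None, 0.0, rng
        )
        cds_b = _nonsyn_noise(cds_b, p.nonsyn_rate, rng)
        ida, idb = f"A_orth{k}", f"B_orth{k}"
        planted_pairs.append((ida, cds_a, idb, cds_b))
        truth.ortholog_pairs[ida] = idb

    decoy_cds: dict[str, list[tuple[str, str]]] = {"A": [], "B": []}
    for genome in ("A", "B"):
        for k in range(p.decoys):
            rng = _rng(config.seed, "nbhd", "decoy", genome, k)
            protein = sample_protein(rng, p.decoy_protein_len)
            decoy_cds[genome].append(
                (f"{genome}_decoy{k}", sample_gene(protein, None, 0.0, rng))
            )

    rng_focal = _rng(config.seed, "nbhd", "focal")
    focal_a = sample_gene(config.protein, None, 0.0, rng_focal)
    focal_b, _ = evolve_synonymous(
        focal_a, p.ortholog_branch_length, None, 0.0, rng_focal
    )

    for genome, focal_cds in (("A", focal_a), ("B", focal_b)):
        members: list[tuple[str, str]] = list(decoy_cds[genome])
        members += [
            (ida, ca) if genome == "A" else (idb, cb)
            for ida, ca, idb, cb in planted_pairs
        ]
        order = _rng(config.seed, "nbhd", "order", genome).permutation(len(members))
        members = [members[i] for i in order]
        mid = len(members) // 2
        members.insert(mid, (f"{genome}_focal", focal_cds))
        pos = 1
        for gene_id, cds in members:
            genomes[genome].append(
                GeneRecord(
                    gene_id=gene_id, species=f"genome{genome}", chrom="chr1",
                    start=pos, end=pos + len(cds) - 1, strand="+", cds=cds,
                )
            )
            pos += len(cds) - 1 + p.spacing_bp
    return genomes["A"], genomes["B"], truth


def evolve_utr(
    utr: str,
    sub_rate: float,
    indel_rate: float,
    mean_indel_len: float,
    rng: np.random.Generator,
    truth: PlantedTruth | None = None,
    name: str = "utr",
) -> str:
    """Diverge a 3'UTR by per-site substitutions and geometric-length indels.

    Substitutions hit each site independently with probability ``sub_rate``
    (always changing the base); the indel count is Poisson with mean
    ``indel_rate * length``, each indel inserting or deleting (50/50) a
    geometric-length segment at a uniform position.
    """
    if not utr:
        raise ValueError("empty UTR")
    bases = np.array(["A", "C", "G", "T"])
    seq = list(utr.upper())
    edits: list[list] = []
    if sub_rate > 0:
        for i in range(len(seq)):
            if rng.random() < sub_rate:
                alternatives = [b for b in bases if b != seq[i]]
                new = alternatives[rng.choice(3)]
                edits.append(["sub", i, seq[i], new])
                seq[i] = new
    if indel_rate > 0:
        n_indels = int(rng.poisson(indel_rate * len(utr)))
        for _ in range(n_indels):
            length = int(rng.geometric(1.0 / mean_indel_len))
            pos = int(rng.integers(0, len(seq) + 1))
            if rng.random() < 0.5:
                segment = "".join(bases[rng.choice(4, size=length)])
                seq[pos:pos] = list(segment)
                edits.append(["ins", pos, segment])
            else:
                removed = "".join(seq[pos : pos + length])
                del seq[pos : pos + length]
                edits.append(["del", pos, removed])
    if truth is not None:
        truth.utr_edits[name] = edits
    return "".join(seq)


def random_utr(rng: np.random.Generator, length: int) -> str:
    bases = np.array(["A", "C", "G", "T"])
    return "".join(bases[rng.choice(4, size=length)])


def mixture_profile(
    profiles: Sequence[CodonUsageProfile], source: str = "genome-wide"
) -> CodonUsageProfile:
    """Equal-weight average of aa_specific profiles — a broad, unspecialised
    codon usage standing in for the whole-genome profile."""
    mixed_freqs: dict[str, float] = {}
    for c in SENSE_CODONS:
        vals = [p.frequencies[c] for p in profiles if c in p.frequencies]
        if vals:
            mixed_freqs[c] = float(np.mean(vals))
    return CodonUsageProfile(
        "aa_specific", {c: 1 for c in mixed_freqs}, mixed_freqs, source
    )


def sample_program_gene_sets(
    config: SimulationConfig,
    program_names: Sequence[str] = ("proliferation", "differentiation"),
) -> tuple[dict[str, CodonUsageProfile], dict[str, list[tuple[str, str]]], Counter]:
    """Program-biased gene sets plus a synthetic genome-wide count table.

    Each program gets a Dirichlet-sampled codon-bias profile; ``n_genes``
    random proteins are sampled per program and their codons drawn fully
    from the program profile. The genome-wide counts pool an equal number
    of genes drawn from the *mixture* of all program profiles (a broad,
    unspecialised usage), emulating a whole-genome codon table.

    Returns (program profiles, per-program ``[(gene_id, cds), ...]``,
    genome-wide pooled codon counts).
    """
    p = config.program
    profiles = {
        name: random_profile(
            _rng(config.seed, "program", name), p.concentration, source=name
        )
        for name in program_names
    }
    gene_cds: dict[str, list[tuple[str, str]]] = {}
    for name in program_names:
        genes = []
        for k in range(p.n_genes):
            rng = _rng(config.seed, "program", name, k)
            protein = sample_protein(rng, p.protein_len)
            genes.append(
                (f"{name}_{k:04d}", sample_gene(protein, profiles[name], 1.0, rng))
            )
        gene_cds[name] = genes

    # genome-wide: genes drawn from the average of the program profiles
    mixed = mixture_profile(list(profiles.values()))
    genomewide: Counter = Counter()
    for k in range(p.n_genes):
        rng = _rng(config.seed, "genomewide", k)
        protein = sample_protein(rng, p.protein_len)
        genomewide.update(codon_counts(sample_gene(protein, mixed, 1.0, rng)))
    return profiles, gene_cds, genomewide
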