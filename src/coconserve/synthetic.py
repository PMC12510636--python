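"""Synthetic inputs with planted ground truth.

Everything the pipeline consumes can be generated here: divergent protein
families for the 13 marker genes (with the true column-tracked alignment
retained), per-genome proteomes of planted orthologs plus shuffled-sequence
decoys, species sets with controlled quinone x dehydrogenase category
frequencies, and exponential/logistic OD600 growth curves with
multiplicative lognormal noise.

Sequence divergence follows the simplest controllable model: each site
accumulates a Poisson(divergence) number of substitutions, each replacing
the residue uniformly among the other 19 (no rate matrix), so the expected
identity to the master is 1/20 + (19/20) exp(-(20/19) d) ~ exp(-d) for
moderate d.  Decoys are within-sequence shuffles of real family members,
preserving the amino-acid multiset exactly while destroying positional
homology.  All generators are deterministic under a fixed integer seed and
keep no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cooccurrence import PANEL_GENES, PATHWAY_GENES, PathwayScheme, call_pathways
from .growth import GrowthCurve
from .seqcluster import AMINO_ACIDS, GAP, SequenceRecord, write_alignment, write_fasta

#: The 13-gene marker panel (property of the co-occurrence scheme).
MARKER_PANEL = PANEL_GENES

#: Default joint category frequencies emulating the observed distribution
#: of quinone pathways and NADH dehydrogenase types across bacterial
#: species: 55% of species carry the NQ pathway, 65.4% of those also carry
#: NDH-2, and 0.9% of all species pair NDH-2 with UQ.
OBSERVED_CATEGORY_FREQS: dict[str, float] = {
    "NQ+NDH2": 0.654 * 0.55,  # 0.3597
    "NQ+NDH1": 0.346 * 0.55,  # 0.1903
    "UQ+NDH1": 1.0 - 0.55 - 0.009,  # 0.4410
    "UQ+NDH2": 0.009,
}

_CATEGORY_TOKENS = {"NQ", "NQC", "NQF", "UQ", "NDH1", "NDH2", "NONE"}


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one divergent protein family."""

    gene_name: str
    master_length: int = 200
    n_members: int = 12
    divergence: float = 0.2
    indel_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.master_length < 10:
            raise ValueError("master_length must be >= 10")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")
        if not (0.0 <= self.indel_rate <= 0.1):
            raise ValueError("indel_rate must be in [0, 0.1]")


@dataclass(frozen=True)
class SpeciesSpec:
    """Composition of one synthetic species' genomes."""

    species_id: str
    genes_present: frozenset[str] = frozenset()
    n_decoys: int = 20
    decoy_mode: str = "shuffled"
    n_genomes: int = 1

    def __post_init__(self) -> None:
        extra = set(self.genes_present) - set(MARKER_PANEL)
        if extra:
            raise ValueError(f"genes outside the 13-marker panel: {sorted(extra)}")
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.decoy_mode not in ("shuffled", "random-background"):
            raise ValueError(f"unknown decoy_mode {self.decoy_mode!r}")


@dataclass
class Family:
    """A generated family: master, members, and the exact alignment."""

    name: str
    master: SequenceRecord
    members: list[SequenceRecord]
    msa: list[tuple[str, str]]  # master first; columns tracked exactly

    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        write_fasta([self.master, *self.members], out_dir / f"{self.name}.fasta")
        write_alignment(self.msa, out_dir / f"{self.name}.aln.fasta")


@dataclass
class SpeciesSet:
    """Generated proteomes plus the planted truth table."""

    proteomes: dict[str, list[SequenceRecord]]  # genome_id -> records
    truth: pd.DataFrame  # one row per species

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for genome_id, records in self.proteomes.items():
            write_fasta(records, out_dir / f"{genome_id}.fasta")
        self.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _mutate_residue(rng: np.random.Generator, residue: str, n_jumps: int) -> str:
    current = residue
    for _ in range(n_jumps):
        choices = [a for a in AMINO_ACIDS if a != current]
        current = choices[rng.integers(0, 19)]
    return current


def generate_family(spec: FamilySpec) -> Family:
    """Generate a master sequence and diverged members with the true MSA.

    Each member is derived from the master site by site: Poisson(d)
    substitution jumps per site, deletion of the site with probability
    indel_rate/2, and an insertion of 1-3 background residues after the
    site with probability indel_rate/2.  The returned alignment has one
    column per master position plus insertion columns, so every member's
    true homology to the master is known exactly.
    """
    rng = np.random.default_rng(spec.seed)
    master_seq = _random_sequence(rng, spec.master_length)
    L = spec.master_length

    # per member: residue (or None if deleted) per master site, plus the
    # insertion string following each site
    member_sites: list[list[str | None]] = []
    member_inserts: list[list[str]] = []
    for _ in range(spec.n_members):
        sites: list[str | None] = []
        inserts: list[str] = []
        for j in range(L):
            if spec.indel_rate > 0 and rng.random() < spec.indel_rate / 2:
                sites.append(None)
            else:
                n_jumps = int(rng.poisson(spec.divergence)) if spec.divergence > 0 else 0
                sites.append(_mutate_residue(rng, master_seq[j], n_jumps))
            if spec.indel_rate > 0 and rng.random() < spec.indel_rate / 2:
                inserts.append(_random_sequence(rng, int(rng.integers(1, 4))))
            else:
                inserts.append("")
        member_sites.append(sites)
        member_inserts.append(inserts)

    # assemble the column-tracked MSA: master column j, then insertion
    # columns sized to the longest insertion after j across members
    rows = ["" for _ in range(spec.n_members + 1)]  # row 0 = master
    for j in range(L):
        rows[0] += master_seq[j]
        for m in range(spec.n_members):
            site = member_sites[m][j]
            rows[m + 1] += site if site is not None else GAP
        width = max((len(member_inserts[m][j]) for m in range(spec.n_members)), default=0)
        if width:
            rows[0] += GAP * width
            for m in range(spec.n_members):
                ins = member_inserts[m][j]
                rows[m + 1] += ins + GAP * (width - len(ins))

    master = SequenceRecord(id=f"{spec.gene_name}_master", residues=master_seq)
    members = []
    for m in range(spec.n_members):
        seq = rows[m + 1].replace(GAP, "")
        members.append(SequenceRecord(id=f"{spec.gene_name}_m{m + 1}", residues=seq))
    msa = [(master.id, rows[0])] + [(mem.id, rows[m + 1]) for m, mem in enumerate(members)]
    return Family(name=spec.gene_name, master=master, members=members, msa=msa)


def generate_marker_families(
    seed: int = 0,
    master_length: int = 200,
    n_members: int = 12,
    divergence: float = 0.2,
    indel_rate: float = 0.01,
) -> dict[str, Family]:
    """One family per marker gene, with per-gene seeds derived from ``seed``."""
    families = {}
    for i, gene in enumerate(MARKER_PANEL):
        spec = FamilySpec(
            gene_name=gene,
            master_length=master_length,
            n_members=n_members,
            divergence=divergence,
            indel_rate=indel_rate,
            seed=(seed * 1009 + i * 7919) % (2**31),
        )
        families[gene] = generate_family(spec)
    return families


# ---------------------------------------------------------------------------
# Proteomes and species sets
# ---------------------------------------------------------------------------


def _shuffled_decoy(rng: np.random.Generator, source: str) -> str:
    arr = np.array(list(source))
    rng.shuffle(arr)
    return "".join(arr)


def generate_proteome(
    spec: SpeciesSpec,
    families: Mapping[str, Family],
    seed: int = 0,
    scheme: PathwayScheme | None = None,
) -> tuple[dict[str, list[SequenceRecord]], dict]:
    """Proteomes for one species plus its planted truth row.

    One family member (never the master) is planted per present gene and
    per genome; decoys are residue shuffles of randomly chosen real
    members (identical amino-acid composition, no positional homology) or
    background-random sequences, per ``decoy_mode``.  Headers follow the
    ``genomeID|speciesID|label`` dialect.
    """
    missing = [g for g in sorted(spec.genes_present) if g not in families]
    if missing:
        raise KeyError(f"no family provided for requested genes: {missing}")
    if spec.n_decoys > 0 and spec.decoy_mode == "shuffled" and not families:
        raise KeyError("shuffled decoys require at least one family as source")
    rng = np.random.default_rng(seed)
    all_members = [m for fam in families.values() for m in fam.members]
    proteomes: dict[str, list[SequenceRecord]] = {}
    for g in range(spec.n_genomes):
        genome_id = f"{spec.species_id}_g{g + 1}"
        records: list[SequenceRecord] = []
        for gene in sorted(spec.genes_present):
            fam = families[gene]
            member = fam.members[rng.integers(0, len(fam.members))]
            records.append(
                SequenceRecord(
                    id=f"{genome_id}|{spec.species_id}|{gene}",
                    residues=member.residues,
                    description=f"planted ortholog of {member.id}",
                )
            )
        for d in range(spec.n_decoys):
            if spec.decoy_mode == "shuffled":
                source = all_members[rng.integers(0, len(all_members))]
                residues = _shuffled_decoy(rng, source.residues)
                desc = f"shuffle of {source.id}"
            else:
                residues = _random_sequence(rng, 200)
                desc = "background-random decoy"
            records.append(
                SequenceRecord(
                    id=f"{genome_id}|{spec.species_id}|decoy{d + 1}",
                    residues=residues,
                    description=desc,
                )
            )
        proteomes[genome_id] = records

    presence = {g: (g in spec.genes_present) for g in MARKER_PANEL}
    call = call_pathways(presence, scheme or PathwayScheme(), species_id=spec.species_id)
    truth_row = {
        "species_id": spec.species_id,
        **presence,
        "nq_classical": call.nq_classical,
        "nq_futalosine": call.nq_futalosine,
        "nq": call.nq,
        "uq": call.uq,
        "ndh1": call.ndh1,
        "ndh2": call.ndh2,
        "quinone_category": call.quinone_category,
        "dh_category": call.dh_category,
    }
    return proteomes, truth_row


def _genes_for_category(label: str, rng: np.random.Generator) -> frozenset[str]:
    """Expand a category label like ``NQ+NDH2`` into a marker-gene set.

    Tokens: NQ (classical or futalosine variant, chosen 50/50), NQC, NQF,
    UQ, NDH1, NDH2, NONE.  Separators ``+`` and the logical-and sign are
    both accepted.
    """
    genes: set[str] = set()
    for token in label.replace("∧", "+").split("+"):
        token = token.strip().upper().replace("-", "")
        if not token:
            continue
        if token not in _CATEGORY_TOKENS:
            raise ValueError(f"unknown category token {token!r} in {label!r}")
        if token == "NONE":
            continue
        elif token == "NQ":
            variant = "nq_classical" if rng.random() < 0.5 else "nq_futalosine"
            genes.update(PATHWAY_GENES[variant])
        elif token == "NQC":
            genes.update(PATHWAY_GENES["nq_classical"])
        elif token == "NQF":
            genes.update(PATHWAY_GENES["nq_futalosine"])
        elif token == "UQ":
            genes.update(PATHWAY_GENES["uq"])
        elif token == "NDH1":
            genes.update(PATHWAY_GENES["ndh1"])
        elif token == "NDH2":
            genes.update(PATHWAY_GENES["ndh2"])
    return frozenset(genes)


def generate_species_set(
    n_species: int,
    category_freqs: Mapping[str, float] | None = None,
    seed: int = 0,
    families: Mapping[str, Family] | None = None,
    n_decoys: int = 20,
    n_genomes: int = 1,
    decoy_mode: str = "shuffled",
) -> SpeciesSet:
    """Draw species categories i.i.d. and realise them as proteomes.

    Category frequencies default to the observed quinone/dehydrogenase
    distribution (:data:`OBSERVED_CATEGORY_FREQS`).  With ``families=None`` only the
    truth table is produced (sequence-free mode, used when downstream
    stages consume presence tables directly).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    freqs = dict(category_freqs) if category_freqs is not None else dict(OBSERVED_CATEGORY_FREQS)
    probs = np.array(list(freqs.values()), dtype=float)
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("category frequencies must lie in [0, 1]")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"category frequencies must sum to 1 (got {probs.sum()})")
    labels = list(freqs.keys())
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(labels), size=n_species, p=probs)

    proteomes: dict[str, list[SequenceRecord]] = {}
    rows = []
    width = max(5, len(str(n_species)))
    for i, ci in enumerate(draws):
        label = labels[int(ci)]
        species_id = f"sp{i:0{width}d}"
        genes = _genes_for_category(label, rng)
        spec = SpeciesSpec(
            species_id=species_id,
            genes_present=genes,
            n_decoys=n_decoys,
            decoy_mode=decoy_mode,
            n_genomes=n_genomes,
        )
        if families is not None:
            prots, row = generate_proteome(
                spec, families, seed=int(rng.integers(0, 2**31))
            )
            proteomes.update(prots)
        else:
            presence = {g: (g in genes) for g in MARKER_PANEL}
            call = call_pathways(presence, species_id=species_id)
            row = {
                "species_id": species_id,
                **presence,
                "nq_classical": call.nq_classical,
                "nq_futalosine": call.nq_futalosine,
                "nq": call.nq,
                "uq": call.uq,
                "ndh1": call.ndh1,
                "ndh2": call.ndh2,
                "quinone_category": call.quinone_category,
                "dh_category": call.dh_category,
            }
        row["category"] = label
        rows.append(row)
    truth = pd.DataFrame(rows)
    return SpeciesSet(proteomes=proteomes, truth=truth)


def truth_presence_sheet(species_set: SpeciesSet) -> pd.DataFrame:
    """Wide per-genome presence sheet derived from the planted truth
    (one genome per species), in the layout the search stage emits."""
    truth = species_set.truth
    sheet = pd.DataFrame(
        {
            "genome_id": truth["species_id"].astype(str) + "_g1",
            "species_id": truth["species_id"],
            **{g: truth[g] for g in MARKER_PANEL},
        }
    )
    return sheet


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


def generate_growth_curve(
    model: str,
    mu: float,
    t_grid: Sequence[float],
    od0: float = 0.02,
    lag: float = 0.0,
    K: float = 1.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    blank: float = 0.0,
) -> GrowthCurve:
    """OD600 time series from an exponential or logistic model.

    Noise is multiplicative lognormal with the stated coefficient of
    variation (mean-one, so ``noise_cv=0`` returns the exact model curve).
    ``mu`` is the specific (exponential) or intrinsic (logistic) rate in
    per-hour; ``lag`` delays growth onset; ``K`` is the logistic carrying
    capacity in OD units.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or not np.all(np.diff(t) > 0):
        raise ValueError("t_grid must be a strictly increasing 1-D grid")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if od0 <= 0:
        raise ValueError("initial OD must be > 0")
    te = np.maximum(t - lag, 0.0)
    if model == "exponential":
        od = od0 * np.exp(mu * te)
    elif model == "logistic":
        if K <= od0:
            raise ValueError("carrying capacity K must exceed the initial OD")
        od = K / (1.0 + ((K - od0) / od0) * np.exp(-mu * te))
    else:
        raise ValueError(f"unknown growth model {model!r}")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma2 = np.log1p(noise_cv**2)
        factors = np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=len(t)))
        od = od * factors
    return GrowthCurve(time_h=t, od600=od + blank, blank=blank)
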