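"""Ground-truthed synthetic study generator.

Emulates a two-reservoir eDNA metabarcoding design: two habitats with
partially overlapping species pools, seven sites per habitat sampled at two
depths, five replicate PCRs per water sample, and Illumina-style merged
amplicon reads carrying 9-bp sample tags and degenerate COI primers around
a 313-bp barcode.

Species barcodes are built from non-stop codons of the invertebrate
mitochondrial code so that every true sequence passes a translation filter
by construction. Read counts follow a lognormal abundance model; detection
failure is modelled explicitly through a per-(species, replicate) dropout
probability, with every non-dropped species guaranteed at least one read
per replicate so that replicate presence in the emitted reads equals the
recorded ground truth.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from edna._seqtools import encode, reverse_complement

BARCODE_LENGTH = 313
TAG_LENGTH = 9

#: degenerate metazoan COI primers (forward, reverse) used to frame reads
FORWARD_PRIMER = "GGWACWGGWTGAACWGTWTAYCCYCC"
REVERSE_PRIMER = "TAIACYTCIGGRTGICCRAARAAYCA"

_INVERT_TABLE = CodonTable.unambiguous_dna_by_id[5]
_SENSE_CODONS = sorted(_INVERT_TABLE.forward_table)  # 62 non-stop codons

_METAZOAN_PHYLA = (
    "Arthropoda", "Chordata", "Mollusca", "Annelida",
    "Rotifera", "Cnidaria", "Porifera",
)
_NONMETAZOAN_PHYLA = ("Chlorophyta", "Bacillariophyta", "Ciliophora")


class PoolGenerationError(RuntimeError):
    """Raised when the requested pool cannot satisfy its spacing invariants."""


@dataclass
class Species:
    species_id: str
    phylum: str
    is_metazoan: bool
    barcode: str
    habitat_membership: str  # "A", "B" or "shared"
    haplotypes: list[str]
    relative_abundance: float


@dataclass
class StudyDesign:
    """Sampling layout: habitats x sites x depths x PCR replicates."""

    habitats: tuple[str, str] = ("Bedok", "Pandan")
    sites_per_habitat: int = 7
    depths: tuple[str, ...] = ("surface", "benthic")
    replicates_per_extract: int = 5
    tag_map: dict[tuple[str, int], tuple[str, str]] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return [
            f"{hab}-S{site + 1}-{depth}"
            for hab in self.habitats
            for site in range(self.sites_per_habitat)
            for depth in self.depths
        ]

    def habitat_of(self, sample: str) -> str:
        return sample.split("-", 1)[0]

    def depth_of(self, sample: str) -> str:
        return sample.rsplit("-", 1)[1]

    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "sample": s,
                "habitat": self.habitat_of(s),
                "site": s.split("-")[1],
                "depth": self.depth_of(s),
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows).set_index("sample")

    def assign_tags(self, seed: int = 0) -> "StudyDesign":
        """Draw unique 9-bp tag pairs for every (sample, replicate)."""
        rng = np.random.default_rng(seed)
        n = len(self.samples) * self.replicates_per_extract
        tags: set[str] = set()
        while len(tags) < 2 * n:
            tags.add("".join(rng.choice(list("ACGT"), TAG_LENGTH)))
        ordered = sorted(tags)
        rng.shuffle(ordered)
        pairs = list(zip(ordered[:n], ordered[n : 2 * n]))
        keys = [
            (s, r)
            for s in self.samples
            for r in range(1, self.replicates_per_extract + 1)
        ]
        self.tag_map = dict(zip(keys, pairs))
        return self

    def write_tag_map(self, path: str | Path) -> None:
        rows = [
            {"sample": s, "replicate": r, "fwd_tag": f, "rev_tag": v}
            for (s, r), (f, v) in self.tag_map.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SpeciesPool:
    species: list[Species]
    occupancy: pd.DataFrame  # species_id x sample, bool
    design: StudyDesign

    def __post_init__(self):
        self._by_id = {sp.species_id: sp for sp in self.species}

    def __len__(self) -> int:
        return len(self.species)

    def __getitem__(self, species_id: str) -> Species:
        return self._by_id[species_id]

    @property
    def metazoans(self) -> list[Species]:
        return [sp for sp in self.species if sp.is_metazoan]

    def reference_records(self):
        """The pool as a reference barcode collection (taxonomy module)."""
        from edna.taxonomy import ReferenceRecord

        return [
            ReferenceRecord(
                ref_id=sp.species_id,
                sequence=sp.barcode,
                species=f"{sp.phylum[:4]}. {sp.species_id}",
                phylum=sp.phylum,
                is_metazoan=sp.is_metazoan,
            )
            for sp in self.species
        ]

    def write_reference_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.reference_records():
                fh.write(
                    f">{rec.ref_id}|{rec.species}|{rec.phylum}|"
                    f"metazoan={int(rec.is_metazoan)}\n{rec.sequence}\n"
                )


@dataclass
class GroundTruth:
    """What the generator actually put into the reads."""

    incidence: pd.DataFrame  # species x sample bool (occupancy)
    replicate_presence: pd.DataFrame  # (species, sample, replicate) -> present
    min_replicates: int = 3

    def detected_incidence(self, min_replicates: int | None = None) -> pd.DataFrame:
        """Species x sample incidence after the >=k-of-n replicate rule."""
        k = self.min_replicates if min_replicates is None else min_replicates
        counts = (
            self.replicate_presence[self.replicate_presence["present"]]
            .groupby(["species_id", "sample"])["replicate"]
            .nunique()
            .unstack(fill_value=0)
        )
        counts = counts.reindex(
            index=self.incidence.index, columns=self.incidence.columns, fill_value=0
        )
        return counts >= k

    def write_tsv(self, path: str | Path) -> None:
        self.replicate_presence.to_csv(path, sep="\t", index=False)


def _random_barcode(rng: np.random.Generator) -> str:
    """313 nt = 104 sense codons + 1 nt, stop-free in frame 0 (invertebrate code)."""
    codons = rng.choice(_SENSE_CODONS, BARCODE_LENGTH // 3)
    return "".join(codons) + rng.choice(list("ACGT"))


def _mutate_codon_safe(barcode: str, rng: np.random.Generator, n_codons: int) -> str:
    """Derive a haplotype by swapping `n_codons` codons for other sense codons
    differing at exactly one position, keeping the frame-0 translation clean."""
    codons = [barcode[i : i + 3] for i in range(0, 312, 3)]
    idx = rng.choice(len(codons), size=n_codons, replace=False)
    for i in idx:
        old = codons[i]
        neighbours = [
            c for c in _SENSE_CODONS
            if sum(a != b for a, b in zip(c, old)) == 1
        ]
        codons[i] = neighbours[rng.integers(len(neighbours))]
    return "".join(codons) + barcode[-1]


def _min_pairwise_mismatches(barcodes: list[str]) -> int:
    enc = encode(barcodes)
    n = len(barcodes)
    best = BARCODE_LENGTH
    step = max(1, 2**24 // (enc.size + 1))
    for i in range(0, n, step):
        diff = (enc[i : i + step, None, :] != enc[None, :, :]).sum(axis=2)
        for r in range(diff.shape[0]):
            diff[r, i + r] = BARCODE_LENGTH  # ignore self
        best = min(best, int(diff.min()))
    return best


def generate_species_pool(
    n_a_only: int,
    n_b_only: int,
    n_shared: int,
    n_contaminant: int = 0,
    seed: int = 0,
    haplotypes_per_species: int = 1,
    occupancy_prob: float = 0.7,
    design: StudyDesign | None = None,
    min_interspecies_dist: float = 0.08,
    max_attempts: int = 20,
) -> SpeciesPool:
    """Draw a species pool with habitat membership and site/depth occupancy.

    Barcodes are random sense-codon sequences; any barcode closer than
    ``min_interspecies_dist`` to an earlier one is redrawn, and generation
    fails explicitly if the spacing cannot be met. Haplotypes within a
    species differ by at most 4 nt (p-distance < 0.013 from the base
    barcode, < 0.026 from each other). Every species occupies each
    site x depth sample of its habitat(s) independently with probability
    ``occupancy_prob`` and is guaranteed at least one occupied sample.
    """
    total = n_a_only + n_b_only + n_shared + n_contaminant
    if min(n_a_only, n_b_only, n_shared, n_contaminant) < 0 or total < 1:
        raise ValueError("species counts must be non-negative and total >= 1")
    rng = np.random.default_rng(seed)
    design = (design or StudyDesign()).assign_tags(seed=seed)

    min_mm = int(np.ceil(min_interspecies_dist * BARCODE_LENGTH)) + 1
    barcodes: list[str] = []
    enc_rows: list[np.ndarray] = []
    for _ in range(total):
        for attempt in range(max_attempts + 1):
            if attempt == max_attempts:
                raise PoolGenerationError(
                    f"cannot place {total} barcodes with pairwise p-distance "
                    f"> {min_interspecies_dist} at length {BARCODE_LENGTH}"
                )
            cand = _random_barcode(rng)
            row = encode([cand])[0]
            if not enc_rows:
                break
            diffs = (np.vstack(enc_rows) != row).sum(axis=1)
            if diffs.min() >= min_mm:
                break
        barcodes.append(cand)
        enc_rows.append(encode([cand])[0])

    memberships = (
        ["A"] * n_a_only + ["B"] * n_b_only + ["shared"] * n_shared
        + ["contaminant"] * n_contaminant
    )
    species: list[Species] = []
    abundances = rng.lognormal(mean=0.0, sigma=1.0, size=total)
    meta_cycle = itertools.cycle(_METAZOAN_PHYLA)
    cont_cycle = itertools.cycle(_NONMETAZOAN_PHYLA)
    for i, (bc, member) in enumerate(zip(barcodes, memberships)):
        is_meta = member != "contaminant"
        haplos = [bc]
        for _ in range(haplotypes_per_species - 1):
            haplos.append(_mutate_codon_safe(bc, rng, n_codons=rng.integers(1, 5)))
        species.append(
            Species(
                species_id=f"sp{i + 1:04d}",
                phylum=next(meta_cycle) if is_meta else next(cont_cycle),
                is_metazoan=is_meta,
                barcode=bc,
                habitat_membership="shared" if member == "contaminant" else member,
                haplotypes=haplos,
                relative_abundance=float(abundances[i]),
            )
        )

    hab_a, hab_b = design.habitats
    samples = design.samples
    occ = pd.DataFrame(False, index=[sp.species_id for sp in species], columns=samples)
    for sp, member in zip(species, memberships):
        eligible = [
            s for s in samples
            if member in ("shared", "contaminant")
            or design.habitat_of(s) == {"A": hab_a, "B": hab_b}[member]
        ]
        flags = rng.random(len(eligible)) < occupancy_prob
        if not flags.any():
            flags[rng.integers(len(eligible))] = True
        occ.loc[sp.species_id, eligible] = flags

    return SpeciesPool(species=species, occupancy=occ, design=design)


def _realise_primer(primer: str, rng: np.random.Generator) -> str:
    """Resolve degenerate/inosine positions to concrete bases (the primer
    pool is a mixture; each amplicon carries one realisation)."""
    from edna._seqtools import IUPAC

    return "".join(
        b if b in "ACGT" else IUPAC[b][rng.integers(len(IUPAC[b]))]
        for b in primer
    )


def _mutate_read(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n = rng.binomial(len(seq), error_rate)
    if n == 0:
        return seq
    pos = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = "ACGT".replace(out[p], "")[rng.integers(3)]
    return "".join(out)


def simulate_reads(
    pool: SpeciesPool,
    design: StudyDesign | None = None,
    error_rate: float = 0.0,
    dropout_prob: float = 0.0,
    chimera_rate: float = 0.0,
    depth_per_replicate: int = 200,
    seed: int = 0,
    min_replicates: int = 3,
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Emit merged-orientation amplicon reads and the matching ground truth.

    Each read is ``fwd_tag + fwd_primer + template + revcomp(rev_primer) +
    revcomp(rev_tag)``. Per replicate, each occupying species survives with
    probability ``1 - dropout_prob``; survivors receive one guaranteed read
    plus a multinomial share of the remaining depth proportional to their
    lognormal abundance (split evenly across haplotypes). A ``chimera_rate``
    fraction of reads is replaced by single-breakpoint splices of two parent
    templates from the same replicate. Deterministic given ``seed``.
    """
    for name, rate in (
        ("error_rate", error_rate),
        ("dropout_prob", dropout_prob),
        ("chimera_rate", chimera_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if depth_per_replicate < 0:
        raise ValueError("depth_per_replicate must be >= 0")

    design = design or pool.design
    if not design.tag_map:
        design.assign_tags(seed=seed)
    rng = np.random.default_rng(seed)

    reads: list[tuple[str, str]] = []
    presence_rows = []
    read_no = 0
    for sample in design.samples:
        occupying = [sp for sp in pool.species if pool.occupancy.loc[sp.species_id, sample]]
        for rep in range(1, design.replicates_per_extract + 1):
            fwd_tag, rev_tag = design.tag_map[(sample, rep)]
            survivors = []
            for sp in occupying:
                present = rng.random() >= dropout_prob if dropout_prob > 0 else True
                if dropout_prob >= 1.0:
                    present = False
                presence_rows.append(
                    {
                        "species_id": sp.species_id,
                        "sample": sample,
                        "replicate": rep,
                        "present": present,
                    }
                )
                if present:
                    survivors.append(sp)
            if not survivors or depth_per_replicate == 0:
                continue
            weights = np.array([sp.relative_abundance for sp in survivors])
            extra = max(depth_per_replicate - len(survivors), 0)
            counts = 1 + rng.multinomial(extra, weights / weights.sum())
            templates: list[str] = []
            for sp, c in zip(survivors, counts):
                h = len(sp.haplotypes)
                for j in range(int(c)):
                    templates.append(sp.haplotypes[j % h])
            rng.shuffle(templates)
            for template in templates:
                if chimera_rate > 0 and rng.random() < chimera_rate and len(survivors) > 1:
                    a, b = rng.choice(len(survivors), size=2, replace=False)
                    bp = int(rng.integers(50, 264))
                    template = (
                        survivors[a].barcode[:bp] + survivors[b].barcode[bp:]
                    )
                insert = _mutate_read(template, error_rate, rng)
                fwd_p = _realise_primer(FORWARD_PRIMER, rng)
                rev_p = _realise_primer(REVERSE_PRIMER, rng)
                read = (
                    fwd_tag + fwd_p + insert
                    + reverse_complement(rev_p) + reverse_complement(rev_tag)
                )
                read_no += 1
                reads.append((f"read_{read_no:07d}", read))

    presence = pd.DataFrame(
        presence_rows, columns=["species_id", "sample", "replicate", "present"]
    )
    truth = GroundTruth(
        incidence=pool.occupancy.copy(),
        replicate_presence=presence,
        min_replicates=min_replicates,
    )
    return reads, truth


def simulate_incidence(
    pool: SpeciesPool,
    dropout_prob: float = 0.0,
    seed: int = 0,
    min_replicates: int = 3,
) -> pd.DataFrame:
    """Species x sample incidence after replicate dropout and the >=k-of-n
    rule, computed without emitting reads.

    Detection of a sequence is a replicate-level event: post-filter presence
    depends only on how many replicate PCRs picked the species up, so for
    incidence-level analyses the read layer can be bypassed. Returns a bool
    DataFrame restricted to metazoan species.
    """
    rng = np.random.default_rng(seed)
    design = pool.design
    n_rep = design.replicates_per_extract
    occ = pool.occupancy
    detections = rng.random((occ.shape[0], occ.shape[1], n_rep)) >= dropout_prob
    detected = (detections.sum(axis=2) >= min_replicates) & occ.to_numpy()
    out = pd.DataFrame(detected, index=occ.index, columns=occ.columns)
    meta_ids = [sp.species_id for sp in pool.metazoans]
    return out.loc[meta_ids]


def write_fastq(
    reads: list[tuple[str, str]], path: str | Path, quality_char: str = "F"
) -> None:
    """Write reads as Phred+33 FASTQ with constant placeholder qualities;
    gzip-compressed when the path ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
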