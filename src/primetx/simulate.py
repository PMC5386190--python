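"""Synthetic two-strain dRNA-seq fixture with planted ground truth.

The generator emulates the design of a double-comparative primary-
transcriptome study: two closely related strains sharing a set of
orthologous protein-coding genes plus strain-specific genes, profiled under
ten growth conditions with one 5'-enriched (treated) library per condition
and one pooled untreated library per strain.

Planted features per strain: gTSSs (a subset conserved across strains, a
subset strain-specific, four of which are silenced in one strain by a
single substitution in the −10 promoter element), antisense and internal
TSSs inside ortholog genes (conserved partners offset by at most 10 nt),
free-standing nTSSs (conserved ones recognisable by sequence), leaderless
genes whose gTSS sits on or within 10 nt of the start codon, and actuaton
arrangements — an abundant annotated sRNA with a sharp 3' coverage drop and
partial read-through into a downstream gene lacking its own gTSS — together
with decoys (a downstream gene that *does* have its own gTSS; an sRNA with
no read-through and no downstream gene).

Read-start counts at planted TSSs follow a negative-binomial model
(per-TSS baseline rate times a per-condition multiplier); a dispersion of
zero switches to deterministic means. Background positions receive low-rate
spurious starts paired with excess coverage so that they fail the
start/coverage ratio rule in expectation. The two genomes share a
coordinate system (substitutions but no structural rearrangements), which
keeps every conserved feature resolvable in both strains.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .io import write_annotation, write_genome, write_ortholog_table, write_table, write_track
from .model import CONDITIONS, GeneAnnotation, GenomeSequence, Library, Track

__all__ = [
    "SimConfig",
    "PlantedTSS",
    "PlantedTU",
    "PlantedActuaton",
    "PlantedSNP",
    "GroundTruth",
    "generate_genome_pair",
    "simulate_read_starts",
    "write_fixture",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

_SENSE_CODONS = None


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        stops = {"TAA", "TAG", "TGA"}
        _SENSE_CODONS = [a + b + c
                         for a in "ACGT" for b in "ACGT" for c in "ACGT"
                         if a + b + c not in stops]
    return _SENSE_CODONS


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the defaults that define it."""

    seed: int = 0
    genome_length: int = 200_000
    n_ortholog_genes: int = 120
    n_strain_specific_genes: int = 15
    n_gtss: int = 100
    n_atss: int = 30
    n_itss: int = 20
    n_ntss: int = 25
    n_conserved_gtss: int = 80
    n_conserved_atss: int = 12
    n_conserved_itss: int = 10
    n_conserved_ntss: int = 15
    n_promoter_snp_cases: int = 4
    n_actuatons: int = 6
    n_decoy_actuatons: int = 6
    n_leaderless: int = 8
    substitution_rate: float = 0.1
    library_size: float = 2_000_000.0
    baseline_median: float = 300.0
    baseline_sigma: float = 0.8
    baseline_clip: tuple = (100.0, 1500.0)
    actuaton_baseline_range: tuple = (5000.0, 10000.0)
    induced_fraction: float = 0.3
    induced_multiplier_range: tuple = (5.0, 30.0)
    condition_sigma: float = 0.6
    nb_dispersion: float = 0.2  # 1/size of the negative binomial; 0 = exact means
    background_per_kb: float = 2.0
    background_mean: float = 3.0
    readthrough_range: tuple = (0.05, 0.4)
    decay_length: float = 30.0
    enrichment_efficiency: float = 1.0
    five_prime_len: int = 50
    treated_body_fraction: float = 0.3
    pad: int = 150
    condition_labels: tuple = CONDITIONS

    def validate(self) -> None:
        if self.n_conserved_gtss > self.n_gtss or self.n_gtss > self.n_ortholog_genes:
            raise ValueError("need n_conserved_gtss <= n_gtss <= n_ortholog_genes")
        n_atss_genes = 2 * self.n_atss - self.n_conserved_atss
        n_itss_genes = 2 * self.n_itss - self.n_conserved_itss
        if n_atss_genes + n_itss_genes > self.n_conserved_gtss:
            raise ValueError(
                "aTSS/iTSS host genes must fit within the conserved-gTSS gene set"
            )
        if self.n_promoter_snp_cases > self.n_gtss - self.n_conserved_gtss:
            raise ValueError("promoter-SNP cases exceed the strain-specific gTSS count")
        if self.n_leaderless > self.n_conserved_gtss:
            raise ValueError("leaderless genes must fit within the conserved-gTSS set")
        if not 0 <= self.nb_dispersion:
            raise ValueError("nb_dispersion must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("baseline_clip", "actuaton_baseline_range",
                    "induced_multiplier_range", "readthrough_range",
                    "condition_labels"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PlantedTSS:
    strain: str
    strand: str
    position: int
    tss_class: str  # gTSS | aTSS | iTSS | nTSS
    gene_id: Optional[str]
    baseline: float
    multipliers: tuple  # one per condition
    pair_id: Optional[str] = None  # shared by conserved partners
    tu_start: int = 0
    tu_end: int = 0
    drop_offset: Optional[int] = None  # actuaton: transcript offset of the sRNA 3' end
    readthrough: Optional[float] = None


@dataclass
class PlantedTU:
    strain: str
    strand: str
    start: int
    end: int
    tss_position: int
    labels: tuple
    gene_ids: tuple = ()
    utr5: Optional[int] = None
    utr3: Optional[int] = None


@dataclass
class PlantedActuaton:
    strain: str
    strand: str
    tss_position: int
    srna_start: int
    srna_end: int
    downstream_gene: Optional[str]
    readthrough: float
    decoy: Optional[str] = None  # None | own_gtss | no_readthrough


@dataclass
class PlantedSNP:
    gene_a: str
    gene_b: str
    strand: str
    tss_position: int
    active_strain: str
    hexamer_active: str
    hexamer_silenced: str
    snp_offset: int  # 0-based within the -12..-7 hexamer


@dataclass
class GroundTruth:
    config: SimConfig
    genome_length: int
    tss: list = field(default_factory=list)
    tus: list = field(default_factory=list)
    actuatons: list = field(default_factory=list)
    leaderless: dict = field(default_factory=dict)  # strain -> [gene_id]
    snps: list = field(default_factory=list)

    def tss_for(self, strain: str) -> list:
        return [t for t in self.tss if t.strain == strain]

    def tus_for(self, strain: str) -> list:
        return [t for t in self.tus if t.strain == strain]

    def conserved_pairs(self, tss_class: str) -> list:
        """(tss_A, tss_B) pairs of the class marked conserved."""
        by_pair: dict[str, dict] = {}
        for t in self.tss:
            if t.tss_class == tss_class and t.pair_id:
                by_pair.setdefault(t.pair_id, {})[t.strain] = t
        return [(d["A"], d["B"]) for d in by_pair.values() if len(d) == 2]


# ---------------------------------------------------------------------------
# layout and sequence construction

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _random_bases(rng, n: int) -> np.ndarray:
    return _ALPHABET[rng.integers(0, 4, size=n)]


def _random_cds(rng, n_codons: int) -> str:
    codons = _sense_codons()
    middle = rng.integers(0, len(codons), size=n_codons - 2)
    return "ATG" + "".join(codons[i] for i in middle) + "TAA"


def _lognormal(rng, median: float, sigma: float, clip: tuple) -> float:
    value = median * math.exp(sigma * rng.standard_normal())
    return float(min(max(value, clip[0]), clip[1]))


def _multipliers(rng, config: SimConfig, induced: bool) -> tuple:
    m = np.exp(config.condition_sigma * rng.standard_normal(len(config.condition_labels)))
    if induced:
        idx = int(rng.integers(0, len(m)))
        lo, hi = config.induced_multiplier_range
        m[idx] *= rng.uniform(lo, hi)
    return tuple(float(x) for x in m)


def _write_hexamer(genome: np.ndarray, position: int, strand: str,
                   hexamer: str = "TATAAT") -> None:
    """Plant a −10 element at −12..−7 relative to a TSS (+1 = TSS)."""
    from .model import revcomp

    if strand == "+":
        start = position - 12
        genome[max(0, start): start + 6] = _encode(hexamer)[max(0, -start):]
    else:
        start = position + 7
        genome[start: start + 6] = _encode(revcomp(hexamer))


def _upstream_span(position: int, strand: str, window: int) -> tuple[int, int]:
    if strand == "+":
        return max(0, position - window), position
    return position + 1, position + 1 + window


def generate_genome_pair(config: SimConfig):
    """Build both genomes, annotations, the ortholog table and the ground truth.

    Returns (genomes, genes, ortholog_id_pairs, truth) where ``genomes`` and
    ``genes`` are dicts keyed by strain "A"/"B".
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    # ---- slot planning -------------------------------------------------
    slots = []  # dicts describing each feature cassette

    def gene_slot(role, idx):
        glen = 3 * int(rng.integers(100, 201))  # 300..600 nt CDS
        u3 = int(min(max(rng.lognormal(math.log(128), 0.5), 30), 250))
        u5 = int(min(max(rng.lognormal(math.log(54), 0.5), 15), 150))
        return {"role": role, "idx": idx, "glen": glen, "u5": u5, "u3": u3,
                "strand": "+" if rng.random() < 0.5 else "-"}

    for i in range(config.n_ortholog_genes):
        slots.append(gene_slot("ortholog", i))
    for strain in "AB":
        for i in range(config.n_strain_specific_genes):
            s = gene_slot(f"specific_{strain}", i)
            slots.append(s)
    n_spec_ntss = config.n_ntss - config.n_conserved_ntss
    for i in range(config.n_conserved_ntss):
        slots.append({"role": "ntss_cons", "idx": i,
                      "len": int(rng.integers(150, 401)),
                      "strand": "+" if rng.random() < 0.5 else "-"})
    for strain in "AB":
        for i in range(n_spec_ntss):
            slots.append({"role": f"ntss_{strain}", "idx": i,
                          "len": int(rng.integers(150, 401)),
                          "strand": "+" if rng.random() < 0.5 else "-"})
    for i in range(config.n_actuatons + config.n_decoy_actuatons):
        decoy = None
        if i >= config.n_actuatons:
            decoy = "own_gtss" if (i - config.n_actuatons) % 2 == 0 else "no_readthrough"
        slots.append({
            "role": "actuaton", "idx": i, "decoy": decoy,
            "srna_len": int(rng.integers(100, 201)),
            "spacer": int(rng.integers(40, 81)),
            "glen": 3 * int(rng.integers(100, 201)),
            "u3": int(rng.integers(40, 101)),
            "strand": "+" if rng.random() < 0.5 else "-",
        })
    # role assignment over ortholog genes (before lengths are frozen: the
    # leaderless genes get their short 5' UTRs here)
    ortho_slots = [sl for sl in slots if sl["role"] == "ortholog"]
    ortho_slots.sort(key=lambda sl: sl["idx"])
    n_spec_gtss = config.n_gtss - config.n_conserved_gtss
    conserved_gtss = ortho_slots[: config.n_conserved_gtss]
    a_only = ortho_slots[config.n_conserved_gtss: config.n_conserved_gtss + n_spec_gtss]
    b_only = ortho_slots[config.n_conserved_gtss + n_spec_gtss:
                         config.n_conserved_gtss + 2 * n_spec_gtss]
    snp_cases = a_only[: config.n_promoter_snp_cases]
    leaderless_slots = conserved_gtss[: config.n_leaderless]
    leaderless_u5 = [0, 10, 3, 7, 5, 2, 8, 6, 4, 1]
    for slot, u5 in zip(leaderless_slots, leaderless_u5):
        slot["u5"] = u5

    # hosts for aTSS/iTSS among conserved-gTSS genes (disjoint sets), taken
    # after the leaderless genes so their short UTRs stay untouched
    hosts = conserved_gtss[config.n_leaderless:] + conserved_gtss[: config.n_leaderless]
    n_spec_atss = config.n_atss - config.n_conserved_atss
    n_spec_itss = config.n_itss - config.n_conserved_itss
    cursor_h = 0

    def take_hosts(n):
        nonlocal cursor_h
        out = hosts[cursor_h: cursor_h + n]
        cursor_h += n
        return out

    atss_cons_hosts = take_hosts(config.n_conserved_atss)
    atss_a_hosts = take_hosts(n_spec_atss)
    atss_b_hosts = take_hosts(n_spec_atss)
    itss_cons_hosts = take_hosts(config.n_conserved_itss)
    itss_a_hosts = take_hosts(n_spec_itss)
    itss_b_hosts = take_hosts(n_spec_itss)

    rng.shuffle(slots)

    cursor = 400
    for slot in slots:
        if slot["role"].startswith("ntss"):
            length = slot["len"]
        elif slot["role"] == "actuaton":
            length = slot["srna_len"] + slot["spacer"] + slot["glen"] + slot["u3"]
            if slot["decoy"] == "no_readthrough":
                length = slot["srna_len"]
        else:
            length = slot["u5"] + slot["glen"] + slot["u3"]
        slot["start"] = cursor
        slot["length"] = length
        cursor += length + config.pad + int(rng.integers(0, 50))
    if cursor + 400 > config.genome_length:
        raise ValueError(
            f"infeasible packing: features need {cursor + 400} nt, "
            f"genome_length is {config.genome_length}"
        )

    # ---- ancestor sequence --------------------------------------------
    L = config.genome_length
    ancestor = _random_bases(rng, L)

    genes: dict[str, list[GeneAnnotation]] = {"A": [], "B": []}
    ortholog_ids: list[tuple[str, str]] = []
    truth = GroundTruth(config=config, genome_length=L,
                        leaderless={"A": [], "B": []})

    protected_identical: list[tuple[int, int]] = []  # spans copied A -> B verbatim
    randomize_other: dict[str, list[tuple[int, int]]] = {"A": [], "B": []}
    pair_counter = 0

    def new_pair_id(prefix: str) -> str:
        nonlocal pair_counter
        pair_counter += 1
        return f"{prefix}{pair_counter:04d}"

    def add_tss(strain, strand, position, tss_class, gene_id, pair_id,
                tu_start, tu_end, baseline=None, induced=None, multipliers=None,
                drop_offset=None, readthrough=None):
        if baseline is None:
            baseline = _lognormal(rng, config.baseline_median,
                                  config.baseline_sigma, config.baseline_clip)
        if multipliers is None:
            if induced is None:
                induced = rng.random() < config.induced_fraction
            multipliers = _multipliers(rng, config, induced)
        t = PlantedTSS(strain=strain, strand=strand, position=position,
                       tss_class=tss_class, gene_id=gene_id,
                       baseline=baseline, multipliers=multipliers,
                       pair_id=pair_id, tu_start=tu_start, tu_end=tu_end,
                       drop_offset=drop_offset, readthrough=readthrough)
        truth.tss.append(t)
        return t

    # ---- ortholog & strain-specific gene cassettes ---------------------
    for slot in slots:
        role = slot["role"]
        if role == "ortholog" or role.startswith("specific_"):
            s = slot["start"]
            strand = slot["strand"]
            if strand == "+":
                gs = s + slot["u5"]
                ge = gs + slot["glen"]
                tss_pos = s
                tu = (s, s + slot["length"])
            else:
                gs = s + slot["u3"]
                ge = gs + slot["glen"]
                tss_pos = s + slot["length"] - 1
                tu = (s, s + slot["length"])
            slot.update(gene_start=gs, gene_end=ge, tss_pos=tss_pos, tu=tu)
            cds = _random_cds(rng, slot["glen"] // 3)
            if strand == "+":
                ancestor[gs:ge] = _encode(cds)
            else:
                from .model import revcomp
                ancestor[gs:ge] = _encode(revcomp(cds))

            if role == "ortholog":
                gid_a = f"A_g{slot['idx']:04d}"
                gid_b = f"B_g{slot['idx']:04d}"
                ortholog_ids.append((gid_a, gid_b))
                for strain, gid in (("A", gid_a), ("B", gid_b)):
                    genes[strain].append(GeneAnnotation(gid, f"chr{strain}", gs, ge, strand))
                slot["gene_ids"] = {"A": gid_a, "B": gid_b}
            else:
                strain = role[-1]
                gid = f"{strain}_s{slot['idx']:04d}"
                genes[strain].append(GeneAnnotation(gid, f"chr{strain}", gs, ge, strand))
                slot["gene_ids"] = {strain: gid}
                randomize_other[strain].append((s, s + slot["length"]))
                _write_hexamer(ancestor, tss_pos, strand)
                t = add_tss(strain, strand, tss_pos, "gTSS", gid, None, *tu)
                truth.tus.append(PlantedTU(strain, strand, tu[0], tu[1], tss_pos,
                                           ("g",), (gid,), slot["u5"], slot["u3"]))

    # gTSS on ortholog genes
    for group, strains in ((conserved_gtss, ("A", "B")),
                           (a_only, ("A",)), (b_only, ("B",))):
        for slot in group:
            strand = slot["strand"]
            tss_pos = slot["tss_pos"]
            _write_hexamer(ancestor, tss_pos, strand)
            pair_id = new_pair_id("g") if len(strains) == 2 else None
            baseline = _lognormal(rng, config.baseline_median,
                                  config.baseline_sigma, config.baseline_clip)
            induced = rng.random() < config.induced_fraction
            multipliers = _multipliers(rng, config, induced)
            slot["gtss_strains"] = strains
            slot["baseline"] = baseline
            for strain in strains:
                gid = slot["gene_ids"][strain]
                add_tss(strain, strand, tss_pos, "gTSS", gid, pair_id,
                        *slot["tu"], baseline=baseline, multipliers=multipliers)
                if slot in leaderless_slots:
                    truth.leaderless[strain].append(gid)
            if len(strains) == 2:
                protected_identical.append(_upstream_span(tss_pos, strand, 50))

    # promoter-SNP silenced cases: gTSS active in A only; window identical
    # except one substitution in the −10 hexamer of strain B
    snp_plan = []
    for slot in snp_cases:
        strand = slot["strand"]
        tss_pos = slot["tss_pos"]
        offset = int(rng.choice([1, 3]))  # TATAAT -> TGTAAT or TATGAT
        snp_plan.append((slot, offset))

    # aTSS / iTSS cassettes
    def plant_internal(slot, tss_class, strains, offset_b):
        strand_gene = slot["strand"]
        glen = slot["glen"]
        gs, ge = slot["gene_start"], slot["gene_end"]
        if tss_class == "aTSS":
            la = int(rng.integers(60, 151))
            o = int(rng.integers(la + 10, glen - 30))
            strand_t = "-" if strand_gene == "+" else "+"
        else:
            li = int(rng.integers(80, 161))
            o = int(rng.integers(20, glen - li - 10))
            strand_t = strand_gene
        pair_id = new_pair_id(tss_class[0]) if len(strains) == 2 else None
        host_baseline = slot["baseline"] * rng.uniform(0.8, 2.0)
        induced = rng.random() < config.induced_fraction
        multipliers = _multipliers(rng, config, induced)
        for strain in strains:
            off = o if strain == "A" or not offset_b else o + offset_b
            off = min(off, glen - 12)
            if strand_gene == "+":
                p = gs + off
            else:
                p = ge - 1 - off
            if tss_class == "aTSS":
                if strand_t == "+":
                    tu = (p, min(p + la, ge))
                else:
                    tu = (max(p - la + 1, gs), p + 1)
            else:
                # internal units run to the host unit's terminator: a 3' end
                # inside the host gene would be indistinguishable from host
                # coverage for any coverage-based segmenter
                if strand_t == "+":
                    tu = (p, slot["tu"][1])
                else:
                    tu = (slot["tu"][0], p + 1)
            _write_hexamer(ancestor, p, strand_t)
            add_tss(strain, strand_t, p, tss_class, slot["gene_ids"][strain],
                    pair_id, *tu, baseline=host_baseline, multipliers=multipliers)
            labels = ("a",) if tss_class == "aTSS" else ("i",)
            truth.tus.append(PlantedTU(strain, strand_t, tu[0], tu[1], p, labels))
            if len(strains) == 2 and strain == "A":
                protected_identical.append(_upstream_span(p, strand_t, 50))

    offsets_cycle = [0, 1, 2, 3, 5, 8, 10]
    for i, slot in enumerate(atss_cons_hosts):
        plant_internal(slot, "aTSS", ("A", "B"), offsets_cycle[i % len(offsets_cycle)])
    for slot in atss_a_hosts:
        plant_internal(slot, "aTSS", ("A",), 0)
    for slot in atss_b_hosts:
        plant_internal(slot, "aTSS", ("B",), 0)
    for i, slot in enumerate(itss_cons_hosts):
        plant_internal(slot, "iTSS", ("A", "B"), offsets_cycle[i % len(offsets_cycle)])
    for slot in itss_a_hosts:
        plant_internal(slot, "iTSS", ("A",), 0)
    for slot in itss_b_hosts:
        plant_internal(slot, "iTSS", ("B",), 0)

    # host-gene TUs gain an 'a' label wherever an antisense unit overlaps
    atss_hosts_by_strain = {"A": atss_cons_hosts + atss_a_hosts,
                            "B": atss_cons_hosts + atss_b_hosts}
    for slot in ortho_slots:
        if "gtss_strains" not in slot:
            continue
        for strain in slot["gtss_strains"]:
            labels = ("g", "a") if slot in atss_hosts_by_strain[strain] else ("g",)
            truth.tus.append(PlantedTU(strain, slot["strand"], *slot["tu"],
                                       slot["tss_pos"], labels,
                                       (slot["gene_ids"][strain],),
                                       slot["u5"], slot["u3"]))

    # ---- nTSS cassettes -------------------------------------------------
    for slot in slots:
        role = slot["role"]
        if not role.startswith("ntss"):
            continue
        s, length, strand = slot["start"], slot["len"], slot["strand"]
        tss_pos = s if strand == "+" else s + length - 1
        tu = (s, s + length)
        _write_hexamer(ancestor, tss_pos, strand)
        if role == "ntss_cons":
            pair_id = new_pair_id("n")
            baseline = _lognormal(rng, config.baseline_median,
                                  config.baseline_sigma, config.baseline_clip)
            multipliers = _multipliers(rng, config, rng.random() < config.induced_fraction)
            for strain in "AB":
                add_tss(strain, strand, tss_pos, "nTSS", None, pair_id, *tu,
                        baseline=baseline, multipliers=multipliers)
                truth.tus.append(PlantedTU(strain, strand, *tu, tss_pos, ("n",)))
            protected_identical.append(_upstream_span(tss_pos, strand, 50))
        else:
            strain = role[-1]
            add_tss(strain, strand, tss_pos, "nTSS", None, None, *tu)
            truth.tus.append(PlantedTU(strain, strand, *tu, tss_pos, ("n",)))
            randomize_other[strain].append((s, s + length))

    # ---- actuaton cassettes ---------------------------------------------
    from .model import revcomp as _rc

    for slot in slots:
        if slot["role"] != "actuaton":
            continue
        s, strand, decoy = slot["start"], slot["strand"], slot["decoy"]
        srna_len = slot["srna_len"]
        length = slot["length"]
        tss_pos = s if strand == "+" else s + length - 1
        tu = (s, s + length)
        _write_hexamer(ancestor, tss_pos, strand)
        if strand == "+":
            srna_span = (s, s + srna_len)
        else:
            srna_span = (s + length - srna_len, s + length)
        lo, hi = config.readthrough_range
        rt = float(rng.uniform(lo, hi)) if decoy != "no_readthrough" else 0.0
        gene_id = None
        if decoy != "no_readthrough":
            if strand == "+":
                gs = s + srna_len + slot["spacer"]
                ge = gs + slot["glen"]
            else:
                ge = s + length - srna_len - slot["spacer"]
                gs = ge - slot["glen"]
            cds = _random_cds(rng, slot["glen"] // 3)
            ancestor[gs:ge] = _encode(cds if strand == "+" else _rc(cds))
            gene_id = f"{{s}}_act{slot['idx']:02d}"
        srna_id = f"{{s}}_srna{slot['idx']:02d}"
        lo_b, hi_b = config.actuaton_baseline_range
        baseline = float(rng.uniform(lo_b, hi_b))
        multipliers = _multipliers(rng, config, rng.random() < config.induced_fraction)
        own_tss_pos = None
        if decoy == "own_gtss":
            own_tss_pos = gs - 40 if strand == "+" else ge - 1 + 40
            _write_hexamer(ancestor, own_tss_pos, strand)
        for strain in "AB":
            gid = gene_id.format(s=strain) if gene_id else None
            sid = srna_id.format(s=strain)
            genes[strain].append(GeneAnnotation(sid, f"chr{strain}", *srna_span,
                                                strand, kind="known_sRNA"))
            if gid:
                genes[strain].append(GeneAnnotation(gid, f"chr{strain}", gs, ge, strand))
            drop = srna_len if decoy != "no_readthrough" else None
            add_tss(strain, strand, tss_pos,
                    "gTSS" if decoy != "no_readthrough" else "nTSS",
                    gid, None, *tu, baseline=baseline, multipliers=multipliers,
                    drop_offset=drop, readthrough=rt if decoy != "no_readthrough" else None)
            if decoy != "no_readthrough":
                labels = ("g",)
                u5 = (gs - tss_pos) if strand == "+" else (tss_pos - (ge - 1))
                truth.tus.append(PlantedTU(strain, strand, *tu, tss_pos, labels,
                                           (gid,), u5, slot["u3"]))
            else:
                truth.tus.append(PlantedTU(strain, strand, *tu, tss_pos, ("n",)))
            if own_tss_pos is not None:
                own_tu = (own_tss_pos, tu[1]) if strand == "+" else (tu[0], own_tss_pos + 1)
                # the decoy's own promoter is strong: it must stay callable
                # on top of the read-through coverage it sits in
                add_tss(strain, strand, own_tss_pos, "gTSS", gid, None, *own_tu,
                        baseline=float(rng.uniform(lo_b, hi_b)))
                truth.tus.append(PlantedTU(strain, strand, *own_tu, own_tss_pos,
                                           ("g",), (gid,), 40, slot["u3"]))
            truth.actuatons.append(
                PlantedActuaton(strain, strand, tss_pos, *srna_span, gid, rt, decoy)
            )

    # ---- derive strain genomes -----------------------------------------
    genome_a = ancestor.copy()
    for span in randomize_other["B"]:  # B-specific features absent from A
        genome_a[span[0]: span[1]] = _random_bases(rng, span[1] - span[0])

    rng_b = np.random.default_rng([config.seed, 1])
    genome_b = ancestor.copy()
    sub_mask = rng_b.random(L) < config.substitution_rate
    shifts = rng_b.integers(1, 4, size=int(sub_mask.sum()))
    idx = np.flatnonzero(sub_mask)
    code = np.searchsorted(_ALPHABET, genome_b[idx])  # ACGT are sorted bytes
    genome_b[idx] = _ALPHABET[(code + shifts) % 4]
    for span in randomize_other["A"]:  # A-specific features absent from B
        genome_b[span[0]: span[1]] = _random_bases(rng_b, span[1] - span[0])
    for span in protected_identical:
        genome_b[span[0]: span[1]] = genome_a[span[0]: span[1]]

    # promoter SNPs: window identical except one −10 substitution
    for slot, hex_offset in snp_plan:
        strand = slot["strand"]
        tss_pos = slot["tss_pos"]
        span = _upstream_span(tss_pos, strand, 50)
        genome_b[span[0]: span[1]] = genome_a[span[0]: span[1]]
        if strand == "+":
            pos = tss_pos - 12 + hex_offset
        else:
            pos = tss_pos + 12 - hex_offset
        hex_a = "TATAAT"
        transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
        complement = {"A": "T", "T": "A", "C": "G", "G": "C"}
        new_letter = transition[hex_a[hex_offset]]  # transcript-level change
        genome_b[pos] = ord(new_letter if strand == "+" else complement[new_letter])
        hex_b = hex_a[:hex_offset] + new_letter + hex_a[hex_offset + 1:]
        truth.snps.append(
            PlantedSNP(gene_a=slot["gene_ids"]["A"], gene_b=slot["gene_ids"]["B"],
                       strand=strand, tss_position=tss_pos, active_strain="A",
                       hexamer_active=hex_a, hexamer_silenced=hex_b,
                       snp_offset=hex_offset)
        )

    genomes = {
        "A": GenomeSequence("A", "chrA", _decode(genome_a)),
        "B": GenomeSequence("B", "chrB", _decode(genome_b)),
    }
    for strain in "AB":
        genes[strain].sort(key=lambda g: (g.start, g.strand))
    truth.tss.sort(key=lambda t: (t.strain, t.position, t.strand))
    truth.tus.sort(key=lambda t: (t.strain, t.start, t.strand))
    return genomes, genes, ortholog_ids, truth


# ---------------------------------------------------------------------------
# read simulation

def _draw_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with dispersion = 1/size; 0 = exact means."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return mean.copy()
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def _tu_profile(t: PlantedTSS, length: int, five_prime_len: int,
                body_fraction: float, treated: bool) -> np.ndarray:
    """Per-position coverage profile along the transcript (index 0 = TSS)."""
    f = np.ones(length)
    if treated:
        f[five_prime_len:] = body_fraction
    if t.drop_offset is not None and t.readthrough is not None:
        f[t.drop_offset:] *= t.readthrough
    return f


def _add_coverage(coverage: np.ndarray, t: PlantedTSS, level: float,
                  profile: np.ndarray, decay_length: float) -> None:
    length = len(profile)
    if t.strand == "+":
        start = t.tu_start
        coverage[start: start + length] += level * profile
        tail_at = start + length
        tail = level * profile[-1] * 0.15 * np.exp(-np.arange(1, 121) / decay_length)
        end = min(len(coverage), tail_at + 120)
        coverage[tail_at:end] += tail[: end - tail_at]
    else:
        end = t.tu_end
        coverage[end - length: end] += level * profile[::-1]
        tail = level * profile[-1] * 0.15 * np.exp(-np.arange(1, 121) / decay_length)
        tail_at = end - length
        start = max(0, tail_at - 120)
        coverage[start: tail_at] += tail[: tail_at - start][::-1]


def simulate_read_starts(truth: GroundTruth, config: SimConfig | None = None) -> dict:
    """Simulate all libraries: strain -> list of 10 treated + 1 untreated."""
    config = config or truth.config
    L = truth.genome_length
    libraries: dict[str, list[Library]] = {}
    for si, strain in enumerate("AB"):
        planted = truth.tss_for(strain)
        libs = []
        for ci, cond in enumerate(config.condition_labels):
            rng = np.random.default_rng([config.seed, 2, si, ci])
            starts = {s: np.zeros(L) for s in "+-"}
            coverage = {s: np.zeros(L) for s in "+-"}
            means = np.array([t.baseline * t.multipliers[ci] for t in planted])
            means *= config.enrichment_efficiency
            counts = _draw_counts(rng, means, config.nb_dispersion)
            for t, c in zip(planted, counts):
                if c <= 0:
                    continue
                starts[t.strand][t.position] += c
                profile = _tu_profile(t, t.tu_end - t.tu_start,
                                      config.five_prime_len,
                                      config.treated_body_fraction, treated=True)
                _add_coverage(coverage[t.strand], t, c, profile, config.decay_length)
            n_bg = int(config.background_per_kb * L / 1000)
            if n_bg > 0:
                for s in "+-":
                    pos = rng.integers(0, L, size=n_bg)
                    cnt = 1 + rng.poisson(max(config.background_mean - 1, 0), size=n_bg)
                    np.add.at(starts[s], pos, cnt)
                    np.add.at(coverage[s], pos, 3 * cnt + rng.poisson(3, size=n_bg))
            tracks = {}
            for s in "+-":
                tracks[("read_starts", s)] = Track(strain, f"chr{strain}", s,
                                                   starts[s], "read_starts")
                tracks[("coverage", s)] = Track(strain, f"chr{strain}", s,
                                                np.maximum(coverage[s], starts[s]),
                                                "coverage")
            libs.append(Library(f"{strain}_{cond}", cond, True, tracks,
                                config.library_size))
        # untreated library: pooled full-length coverage, no 5' enrichment
        rng = np.random.default_rng([config.seed, 3, si])
        coverage = {s: np.zeros(L) for s in "+-"}
        for t in planted:
            pooled = t.baseline * float(np.mean(t.multipliers))
            profile = _tu_profile(t, t.tu_end - t.tu_start,
                                  config.five_prime_len, 1.0, treated=False)
            _add_coverage(coverage[t.strand], t, pooled, profile, config.decay_length)
        tracks = {}
        for s in "+-":
            cov = coverage[s]
            if config.nb_dispersion > 0:
                noisy = cov > 0
                cov = cov.copy()
                cov[noisy] *= rng.gamma(25.0, 1.0 / 25.0, size=int(noisy.sum()))
            tracks[("coverage", s)] = Track(strain, f"chr{strain}", s, cov, "coverage")
            tracks[("read_starts", s)] = Track(strain, f"chr{strain}", s,
                                               cov / 100.0, "read_starts")
        libs.append(Library(f"{strain}_untreated", "untreated", False, tracks,
                            config.library_size))
        libraries[strain] = libs
    return libraries


# ---------------------------------------------------------------------------
# fixture emission

_STRAND_NAME = {"+": "fwd", "-": "rev"}


def write_fixture(config: SimConfig, outdir) -> dict:
    """Generate and write the complete two-strain fixture.

    Returns a manifest dict with the in-memory objects for convenience.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    genomes, genes, ortholog_ids, truth = generate_genome_pair(config)
    libraries = simulate_read_starts(truth, config)

    for strain in "AB":
        write_genome(genomes[strain], outdir / f"{strain}.fasta")
        write_annotation(genes[strain], outdir / f"{strain}.gff3")
        for lib in libraries[strain]:
            for (sem, s), track in sorted(lib.tracks.items()):
                name = f"{strain}.{lib.condition}.{sem}.{_STRAND_NAME[s]}.bedgraph"
                write_track(track, outdir / "tracks" / name)
    write_ortholog_table(ortholog_ids, outdir / "orthologs.tsv")
    config.to_yaml(outdir / "config.yaml")
    write_table(
        [{"strain": strain, "condition": lib.condition,
          "treated": int(lib.treated), "raw_total": lib.raw_total}
         for strain in "AB" for lib in libraries[strain]],
        outdir / "libraries.tsv",
        columns=["strain", "condition", "treated", "raw_total"],
    )

    rows = [
        {
            "strain": t.strain, "strand": t.strand, "position": t.position + 1,
            "class": t.tss_class, "gene_id": t.gene_id or "",
            "baseline": t.baseline, "pair_id": t.pair_id or "",
            "tu_start": t.tu_start + 1, "tu_end": t.tu_end,
        }
        for t in truth.tss
    ]
    write_table(rows, outdir / "truth_tss.tsv",
                columns=["strain", "strand", "position", "class", "gene_id",
                         "baseline", "pair_id", "tu_start", "tu_end"])
    write_table(
        [{"strain": a.strain, "strand": a.strand, "tss_position": a.tss_position + 1,
          "srna_start": a.srna_start + 1, "srna_end": a.srna_end,
          "downstream_gene": a.downstream_gene or "",
          "readthrough": a.readthrough, "decoy": a.decoy or ""}
         for a in truth.actuatons],
        outdir / "truth_actuatons.tsv",
        columns=["strain", "strand", "tss_position", "srna_start", "srna_end",
                 "downstream_gene", "readthrough", "decoy"],
    )
    return {"genomes": genomes, "genes": genes, "ortholog_ids": ortholog_ids,
            "truth": truth, "libraries": libraries}
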