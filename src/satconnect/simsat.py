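"""Satellite evolution simulator: molecular drive vs a frozen satellite.

Monomer libraries evolve along a rooted species tree.  Substitutions
accumulate per branch at a per-site rate (Jukes-Cantor-like: uniform choice
among the three alternative bases, no indels).  The two regimes differ in
what else happens:

* ``drive`` — gene-conversion-like homogenisation events (a random donor
  monomer overwrites a random recipient within the lineage's library) occur
  at ``homogenization_rate`` events per monomer per branch-unit.  This is
  the concerted-evolution engine: within-species copies stay homogeneous
  while species diverge from each other, so intraspecific identity exceeds
  interspecific identity and read clusters are species-specific.

* ``frozen`` — no homogenisation; a declared fraction of sites is
  constrained (substitution rate ~0 there), modelling a conserved
  satellite.  Intraspecific and interspecific identity stay nearly equal
  and high, so clusters intermingle reads from every species.

Monomer libraries are assembled into tandem arrays (optionally ablating
each copy's restriction site with a per-copy probability, which produces
the monomer-periodic digest ladder), and paired-end reads with a uniform
substitution-error model are sampled from the arrays.  Everything is
deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np

from ._align import revcomp
from .errors import SatconnectError
from .seqio import ReadPair, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_TREE = (
    "((maniculatus:1.0,polionotus:1.0):1.0,"
    "(californicus:1.0,leucopus:1.0):1.0);"
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated satellite system.

    Rates are per branch-unit of the newick tree.  The defaults emulate a
    four-species rodent clade with ~345-bp centromeric monomers; drive-mode
    rates are chosen so species diverge well past the 95-99% clustering
    thresholds while homogenisation keeps within-species copies above them,
    and frozen-mode constraint keeps all identities high and nearly equal.
    """

    mode: str = "drive"  # 'drive' or 'frozen'
    tree: str = DEFAULT_TREE
    monomer_length: int = 345
    ancestral_monomer: str | None = None
    library_size: int = 20
    substitution_rate: float = 0.05   # substitutions/site/branch-unit
    homogenization_rate: float = 10.0  # events/monomer/branch-unit (drive)
    constrained_fraction: float = 0.9  # immutable site fraction (frozen)
    frozen_rate_scale: float = 0.0     # residual rate at constrained sites
    copies_per_array: int = 60
    site_ablation_prob: float = 0.0
    restriction_site: str = "CCGG"
    read_length: int = 100
    insert_size: int = 160
    error_rate: float = 0.005
    n_pairs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"drive", "frozen"}:
            raise ValueError("mode must be 'drive' or 'frozen'")
        if self.mode == "drive" and self.homogenization_rate <= 0:
            raise ValueError("drive mode requires homogenization_rate > 0")
        for name in ("substitution_rate", "homogenization_rate",
                     "site_ablation_prob", "error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length")


def _random_monomer(length: int, rng: np.random.Generator, site: str) -> str:
    """Random monomer with exactly one restriction site, even in tandem.

    Chance occurrences are scrubbed, one site is planted, and the
    head-to-tail junction is kept site-free so a tandem array of intact
    copies digests into exact monomer-length fragments.
    """
    arr = rng.choice(_BASES, size=length)
    seq = arr.tobytes().decode()
    # remove chance occurrences, then plant one site at a fixed offset
    while site in seq:
        seq = seq.replace(site, site[0] + "A" + site[2:], 1)
    pos = length // 3
    seq = seq[:pos] + site + seq[pos + len(site):]
    k = len(site)
    while site in seq[-(k - 1):] + seq[: k - 1]:  # junction-spanning site
        last = rng.choice(_BASES)
        seq = seq[:-1] + chr(last)
    return seq


def _mutate(
    seq: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    mutable: np.ndarray | None = None,
) -> None:
    """In-place substitutions at ``rate`` per site (restricted to mutable sites)."""
    if rate <= 0:
        return
    hits = rng.random(seq.size) < rate
    if mutable is not None:
        hits &= mutable
    idx = np.flatnonzero(hits)
    for i in idx:
        choices = _BASES[_BASES != seq[i]]
        seq[i] = rng.choice(choices)


def evolve_library(config: SimulationConfig) -> dict[str, list[SequenceRecord]]:
    """Evolve the ancestral monomer into per-species monomer libraries."""
    rng = np.random.default_rng(config.seed)
    if config.ancestral_monomer is not None:
        ancestor = config.ancestral_monomer.upper()
    else:
        ancestor = _random_monomer(config.monomer_length, rng,
                                   config.restriction_site)
    anc_arr = np.frombuffer(ancestor.encode(), dtype=np.uint8).copy()

    mutable: np.ndarray | None = None
    if config.mode == "frozen":
        mutable = np.ones(anc_arr.size, dtype=bool)
        n_constrained = int(round(config.constrained_fraction * anc_arr.size))
        constrained = rng.choice(anc_arr.size, size=n_constrained, replace=False)
        mutable[constrained] = False

    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    libraries: dict[str, list[SequenceRecord]] = {}

    # branches are discretised so substitution and homogenisation interleave
    # (an ongoing balance, not mutate-everything-then-homogenise)
    segment = 0.1

    def _evolve_branch(lib: list[np.ndarray], length: float) -> None:
        remaining = length
        while remaining > 1e-12:
            dt = min(segment, remaining)
            remaining -= dt
            rate = config.substitution_rate * dt
            for monomer in lib:
                if config.mode == "frozen":
                    _mutate(monomer, rate, rng, mutable)
                    if config.frozen_rate_scale > 0:
                        _mutate(monomer, rate * config.frozen_rate_scale,
                                rng, ~mutable)
                else:
                    _mutate(monomer, rate, rng)
            if config.mode == "drive" and config.homogenization_rate > 0:
                n_events = rng.poisson(
                    config.homogenization_rate * dt * len(lib)
                )
                for _ in range(n_events):
                    donor = rng.integers(len(lib))
                    recipient = rng.integers(len(lib))
                    lib[recipient] = lib[donor].copy()

    def descend(node, library: list[np.ndarray]) -> None:
        for child in node.child_nodes():
            length = child.edge.length or 0.0
            lib = [m.copy() for m in library]
            _evolve_branch(lib, length)
            if child.is_leaf():
                name = child.taxon.label.replace(" ", "_")
                libraries[name] = [
                    SequenceRecord(
                        id=f"{name}_mono{i:03d}",
                        bases=m.tobytes().decode(),
                        source=name,
                    )
                    for i, m in enumerate(lib)
                ]
            else:
                descend(child, lib)

    root_library = [anc_arr.copy() for _ in range(config.library_size)]
    descend(tree.seed_node, root_library)
    if not libraries:
        raise SatconnectError("tree has no leaves")
    return libraries


def build_array(
    monomers: Sequence[SequenceRecord],
    copies: int,
    site_ablation_prob: float = 0.0,
    seed: int = 0,
    restriction_site: str = "CCGG",
    array_id: str = "array",
    source: str | None = None,
) -> SequenceRecord:
    """Head-to-tail tandem array of monomers drawn with replacement.

    Each copy's restriction site is ablated (one substitution inside the
    site) independently with ``site_ablation_prob``.
    """
    if copies < 1:
        raise ValueError("copies must be >= 1")
    rng = np.random.default_rng(seed)
    chunks: list[str] = []
    for _ in range(copies):
        monomer = monomers[rng.integers(len(monomers))].bases
        if site_ablation_prob > 0 and rng.random() < site_ablation_prob:
            # substitute inside the site until none remains (a substitution
            # there can recreate a shifted site against the flanking bases)
            while (pos := monomer.find(restriction_site)) != -1:
                offset = int(rng.integers(len(restriction_site)))
                old = monomer[pos + offset]
                new = rng.choice([b for b in "ACGT" if b != old])
                monomer = (
                    monomer[: pos + offset]
                    + str(new)
                    + monomer[pos + offset + 1:]
                )
        chunks.append(monomer)
    return SequenceRecord(
        id=array_id, bases="".join(chunks),
        source=source or (monomers[0].source if monomers else None),
    )


def simulate_reads(
    array: SequenceRecord,
    config: SimulationConfig,
    seed: int | None = None,
    id_prefix: str | None = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord], list[dict]]:
    """Sample paired-end reads uniformly from a tandem array.

    Mate 1 is the insert prefix, mate 2 the reverse complement of the
    insert suffix; substitution errors at ``error_rate``; constant Q30
    qualities.  Returns (mates 1, mates 2, truth rows); truth rows record
    read id, source and array start coordinate.
    """
    if len(array.bases) < config.insert_size:
        raise SatconnectError("array shorter than insert size")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    prefix = id_prefix or (array.source or array.id)
    fwd: list[SequenceRecord] = []
    rev: list[SequenceRecord] = []
    truth: list[dict] = []
    q30 = (30,) * config.read_length
    max_start = len(array.bases) - config.insert_size
    for i in range(config.n_pairs):
        start = int(rng.integers(max_start + 1))
        insert = array.bases[start : start + config.insert_size]
        mate1 = _with_errors(insert[: config.read_length], config.error_rate, rng)
        mate2 = _with_errors(
            revcomp(insert[-config.read_length:]), config.error_rate, rng
        )
        rid = f"{prefix}_read{i:05d}"
        fwd.append(SequenceRecord(id=f"{rid}/1", bases=mate1, quals=q30,
                                  source=array.source))
        rev.append(SequenceRecord(id=f"{rid}/2", bases=mate2, quals=q30,
                                  source=array.source))
        truth.append({"read_id": rid, "source": array.source or array.id,
                      "array_start": start})
    return fwd, rev, truth


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    _mutate(arr, rate, rng)
    return arr.tobytes().decode()


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces."""

    config: SimulationConfig
    libraries: dict[str, list[SequenceRecord]]
    arrays: dict[str, SequenceRecord]
    reads_fwd: list[SequenceRecord]
    reads_rev: list[SequenceRecord]
    truth: list[dict]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Full run: libraries -> one array per species -> paired reads."""
    libraries = evolve_library(config)
    arrays: dict[str, SequenceRecord] = {}
    reads_fwd: list[SequenceRecord] = []
    reads_rev: list[SequenceRecord] = []
    truth: list[dict] = []
    for k, (species, monomers) in enumerate(sorted(libraries.items())):
        arrays[species] = build_array(
            monomers,
            copies=config.copies_per_array,
            site_ablation_prob=config.site_ablation_prob,
            seed=config.seed + 1000 + k,
            restriction_site=config.restriction_site,
            array_id=f"{species}_array",
            source=species,
        )
        fwd, rev, rows = simulate_reads(
            arrays[species], config, seed=config.seed + 2000 + k
        )
        reads_fwd.extend(fwd)
        reads_rev.extend(rev)
        truth.extend(rows)
    return SimulatedDataset(
        config=config,
        libraries=libraries,
        arrays=arrays,
        reads_fwd=reads_fwd,
        reads_rev=reads_rev,
        truth=truth,
    )


def make_two_family_fixture(
    n_per_family: int = 15,
    length: int = 345,
    within_divergence: int = 1,
    between_divergence: int = 35,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Two planted monomer families with controlled edit distances.

    Family members differ from their family founder by exactly
    ``within_divergence`` substitutions at member-specific positions; the
    two founders differ by exactly ``between_divergence`` substitutions.
    Returns (records labelled by family, truth mapping id -> family index).
    """
    rng = np.random.default_rng(seed)
    founder_a = rng.choice(_BASES, size=length)
    founder_b = founder_a.copy()
    pos = rng.choice(length, size=between_divergence, replace=False)
    for p in pos:
        choices = _BASES[_BASES != founder_b[p]]
        founder_b[p] = rng.choice(choices)
    records: list[SequenceRecord] = []
    truth: dict[str, int] = {}
    for family, founder in enumerate((founder_a, founder_b)):
        for i in range(n_per_family):
            member = founder.copy()
            mpos = rng.choice(length, size=within_divergence, replace=False)
            for p in mpos:
                choices = _BASES[_BASES != member[p]]
                member[p] = rng.choice(choices)
            rid = f"fam{family}_seq{i:02d}"
            records.append(
                SequenceRecord(id=rid, bases=member.tobytes().decode(),
                               source=f"fam{family}")
            )
            truth[rid] = family
    return records, truth
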