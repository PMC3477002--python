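"""Synthetic labeled communities with tunable taxonomic compositional signal.

The generator plants a balanced taxonomy (a branching factor per rank),
equips every node with an order-k Markov model of nucleotide composition
obtained by jittering its parent's parameters, samples genomes from the
species-level models, and optionally shears genomes into ~400 bp
fragments under a simple, fully parameterized sequencing-error model
(substitutions, homopolymer-run extensions, and indels — an explicit,
transparent simplification of pyrosequencer-style read simulation, not a
reimplementation of any particular simulator).

The per-level ``divergence`` knob is the "phylogenetic signal": 0 makes
all species compositionally identical (scores should collapse to chance
agreement), large values at a rank make that rank's clades trivially
separable.  Everything is deterministic given the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .taxonomy import LabeledDataset, Lineage, SequenceRecord, N_LEVELS

__all__ = [
    "PlantedTaxonomy",
    "SignalModel",
    "FragmentModel",
    "generate_taxonomy",
    "generate_genomes",
    "generate_fragments",
    "default_community",
]

_LEVEL_PREFIX = ("do", "ph", "cl", "or", "fa", "ge", "sp")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedTaxonomy:
    """A balanced planted taxonomy.

    ``branching[t]`` is the number of children every node at rank ``t``
    has (domain→species); the number of species equals the product.
    Each node's identifier embeds its path (e.g. ``sp0.1.0.0.0.2.1``),
    so identifiers are globally unique and slot-wise comparison behaves
    like comparison of NCBI taxids.
    """

    branching: tuple[int, ...]
    species_lineages: tuple[Lineage, ...]
    seed: int

    @property
    def n_species(self) -> int:
        return len(self.species_lineages)


@dataclass(frozen=True)
class SignalModel:
    """Order-k Markov composition model with per-rank divergence along a
    dominant axis.

    Composition variation across real microbial clades is dominated by a
    single axis (G+C content), with the consequence that clades from
    very different parts of the taxonomy frequently *converge* to
    near-identical composition.  The model reproduces both properties:
    one shared unit direction in transition-logit space is drawn per
    community, and the children of every tree node are spread along it
    at centered, evenly spaced offsets ``(c - (b-1)/2)`` scaled by the
    rank's divergence, plus a small Gaussian jitter
    (``offset_jitter × N(0,1)``, also along the axis, renormalized via
    softmax so rows stay valid distributions for any magnitude).

    ``divergence_per_level[t]`` is the sibling gap, in logit units, at
    rank ``t`` (domain→species).  The defaults form a ladder in which a
    rank's child span exceeds its parent's sibling gap, so cousin clades
    interleave along the axis — separable within their own clade, yet
    aliasing each other community-wide.  ``order`` defaults to 2 —
    dinucleotide structure, enough to create word-level signal for
    n ≥ 2 while leaving mononucleotide frequencies nearly uninformative.
    """

    order: int = 2
    divergence_per_level: tuple[float, ...] = (2.0, 0.65, 0.4, 0.2, 0.12, 0.08, 0.05)
    seed: int = 0
    base_logit_scale: float = 0.2
    offset_jitter: float = 0.1

    def __post_init__(self):
        if self.order < 0:
            raise ValueError("Markov order must be ≥ 0")
        if len(self.divergence_per_level) != N_LEVELS:
            raise ValueError(f"divergence_per_level needs {N_LEVELS} values")
        if any(d < 0 for d in self.divergence_per_level):
            raise ValueError("divergence values must be ≥ 0")


@dataclass(frozen=True)
class FragmentModel:
    """Simple per-base error model for ~400 bp shotgun fragments.

    Rates are per base (``homopolymer_extension_rate`` per run of
    identical bases) and may reach 1.0 (every position affected).
    Defaults emulate a low-error pyrosequencer-like profile dominated by
    homopolymer-length errors.
    """

    mean_length: float = 400.0
    length_sd: float = 40.0
    substitution_rate: float = 5e-4
    insertion_rate: float = 5e-4
    deletion_rate: float = 5e-4
    homopolymer_extension_rate: float = 0.01
    seed: int = 0
    min_length: int = 20  # ≥ 2 × the largest word length in use

    def __post_init__(self):
        for r in (
            self.substitution_rate,
            self.insertion_rate,
            self.deletion_rate,
            self.homopolymer_extension_rate,
        ):
            if not (0.0 <= r <= 1.0):
                raise ValueError("error rates must lie in [0, 1]")
        if self.mean_length < 2 * self.min_length / 2:
            raise ValueError("mean_length too small for the configured min_length")


def generate_taxonomy(branching, seed: int = 0) -> PlantedTaxonomy:
    """Plant a balanced taxonomy with the given children-per-rank counts."""
    branching = tuple(int(b) for b in branching)
    if len(branching) != N_LEVELS or any(b < 1 for b in branching):
        raise ValueError(f"branching needs {N_LEVELS} positive integers, got {branching!r}")

    lineages: list[Lineage] = []

    def walk(path: tuple[int, ...]):
        t = len(path)
        if t == N_LEVELS:
            lineages.append(
                tuple(
                    _LEVEL_PREFIX[i] + ".".join(str(p) for p in path[: i + 1])
                    for i in range(N_LEVELS)
                )
            )
            return
        for c in range(branching[t]):
            walk(path + (c,))

    walk(())
    return PlantedTaxonomy(branching=branching, species_lineages=tuple(lineages), seed=seed)


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@njit(cache=True)
def _sample_chain(cdf: np.ndarray, order: int, length: int, seed: int) -> np.ndarray:
    """Sample a base-code sequence from a Markov chain given row-wise CDFs."""
    np.random.seed(seed)
    out = np.empty(length, dtype=np.int64)
    n_states = cdf.shape[0]
    state = 0
    for i in range(length):
        if i < order:
            c = np.random.randint(0, 4)
        else:
            u = np.random.random()
            row = cdf[state]
            c = 0
            while c < 3 and row[c] < u:
                c += 1
        out[i] = c
        state = (state * 4 + c) % n_states
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _species_logits(
    taxonomy: PlantedTaxonomy, signal: SignalModel
) -> dict[tuple[int, ...], np.ndarray]:
    """Transition logits per species path: walk the planted tree, spreading
    each node's children along the community's divergence axis at centered
    even offsets (plus jitter) scaled by the child rank's divergence."""
    k_states = 4 ** signal.order
    root_rng = np.random.default_rng([signal.seed, 0])
    root = root_rng.normal(0.0, signal.base_logit_scale, size=(k_states, 4))
    axis = root_rng.normal(0.0, 1.0, size=(k_states, 4))
    axis /= np.sqrt((axis ** 2).mean())

    out: dict[tuple[int, ...], np.ndarray] = {}

    def walk(path: tuple[int, ...], logits: np.ndarray):
        t = len(path)
        if t == N_LEVELS:
            out[path] = logits
            return
        b = taxonomy.branching[t]
        for c in range(b):
            child_path = path + (c,)
            # Independent, traversal-order-free stream per node.
            rng = np.random.default_rng([signal.seed, 1, t, *child_path])
            coef = (c - (b - 1) / 2) + signal.offset_jitter * rng.normal()
            walk(child_path, logits + signal.divergence_per_level[t] * coef * axis)

    walk((), root)
    return out


def generate_genomes(
    taxonomy: PlantedTaxonomy,
    signal: SignalModel,
    genome_length: int = 200_000,
    per_species_count: int = 2,
    seed: int = 0,
) -> LabeledDataset:
    """Sample ``per_species_count`` genomes per species of the planted tree.

    Each species' genomes are drawn from its own Markov model; byte-level
    deterministic given ``(signal.seed, seed)``.
    """
    if genome_length < 1000:
        raise ValueError("genome_length must be ≥ 1000")
    logits = _species_logits(taxonomy, signal)
    records = []
    for sp_idx, lineage in enumerate(taxonomy.species_lineages):
        path = tuple(
            int(p) for p in lineage[-1][len(_LEVEL_PREFIX[-1]):].split(".")
        )
        cdf = np.cumsum(_softmax_rows(logits[path]), axis=1)
        for rep in range(per_species_count):
            chain_seed = (seed * 1_000_003 + sp_idx * 131 + rep) % (2**31 - 1)
            codes = _sample_chain(cdf, signal.order, genome_length, chain_seed)
            records.append(
                SequenceRecord(
                    id=f"G{sp_idx:04d}.{rep:02d}",
                    sequence=_codes_to_str(codes),
                    lineage=lineage,
                )
            )
    return LabeledDataset(records, dataset_id="genomes")


def _runs(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode: (run start indices, run lengths)."""
    if codes.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    change = np.flatnonzero(np.diff(codes) != 0) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [codes.size])))
    return starts, lengths


def _mutate(codes: np.ndarray, model: FragmentModel, rng: np.random.Generator) -> np.ndarray:
    # substitutions
    if model.substitution_rate > 0:
        hit = rng.random(codes.size) < model.substitution_rate
        if hit.any():
            codes = codes.copy()
            codes[hit] = (codes[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    # homopolymer-run extension: duplicate the last base of affected runs
    if model.homopolymer_extension_rate > 0:
        starts, lengths = _runs(codes)
        ext = rng.random(starts.size) < model.homopolymer_extension_rate
        if ext.any():
            ends = starts[ext] + lengths[ext] - 1
            codes = np.insert(codes, ends + 1, codes[ends])
    # indels
    if model.deletion_rate > 0:
        keep = rng.random(codes.size) >= model.deletion_rate
        codes = codes[keep]
    if model.insertion_rate > 0:
        ins = rng.random(codes.size + 1) < model.insertion_rate
        if ins.any():
            pos = np.flatnonzero(ins)
            codes = np.insert(codes, pos, rng.integers(0, 4, size=pos.size))
    return codes


def generate_fragments(
    genomes: LabeledDataset,
    count: int,
    model: FragmentModel,
    abundance: np.ndarray | None = None,
) -> LabeledDataset:
    """Shear ``genomes`` into ``count`` error-bearing fragments.

    Source genomes are drawn uniformly unless an ``abundance`` weight
    vector (one weight per genome) is given; positions are uniform along
    the genome.  Lengths are Normal(mean_length, length_sd) truncated to
    ``[min_length, genome length]``.  Errors are applied in the order
    substitution → homopolymer extension → indels.  Each fragment
    inherits its source genome's lineage and records the source ID.
    """
    n_genomes = len(genomes)
    if n_genomes == 0:
        raise ValueError("no genomes to fragment")
    lengths_ok = min(len(r.sequence) for r in genomes)
    if lengths_ok < model.min_length:
        raise ValueError("every genome must be at least min_length long")

    rng = np.random.default_rng(model.seed)
    if abundance is None:
        p = None
    else:
        abundance = np.asarray(abundance, dtype=float)
        if abundance.shape != (n_genomes,) or (abundance < 0).any() or abundance.sum() <= 0:
            raise ValueError("abundance must be a non-negative weight per genome")
        p = abundance / abundance.sum()

    # Pre-map genome sequences to code arrays once.
    code_lut = np.full(256, -1, dtype=np.int64)
    for b, c in zip(b"ACGT", range(4)):
        code_lut[b] = c
    genome_codes = [
        code_lut[np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8)]
        for r in genomes
    ]

    picks = rng.choice(n_genomes, size=count, p=p)
    raw_lengths = rng.normal(model.mean_length, model.length_sd, size=count)

    records = []
    for i in range(count):
        g = int(picks[i])
        src = genomes.records[g]
        gcodes = genome_codes[g]
        frag_len = int(round(raw_lengths[i]))
        frag_len = max(model.min_length, min(frag_len, gcodes.size))
        pos = int(rng.integers(0, gcodes.size - frag_len + 1))
        codes = _mutate(gcodes[pos : pos + frag_len], model, rng)
        records.append(
            SequenceRecord(
                id=f"F{i:06d}",
                sequence=_codes_to_str(codes.astype(np.int64)),
                lineage=src.lineage,
                source_id=src.id,
            )
        )
    return LabeledDataset(records, dataset_id="fragments")


def default_community(
    seed: int = 0,
    branching=(2, 4, 2, 3, 1, 1, 1),
    genome_length: int = 200_000,
    per_species_count: int = 2,
    divergence_per_level: tuple[float, ...] | None = None,
) -> tuple[PlantedTaxonomy, LabeledDataset]:
    """Convenience: a 48-species community (2 domains × 4 phyla × 2 classes ×
    3 orders, one species per order) with the default divergence ladder."""
    tax = generate_taxonomy(branching, seed=seed)
    signal = SignalModel(
        seed=seed,
        **(
            {}
            if divergence_per_level is None
            else {"divergence_per_level": tuple(divergence_per_level)}
        ),
    )
    genomes = generate_genomes(
        tax, signal, genome_length=genome_length,
        per_species_count=per_species_count, seed=seed,
    )
    return tax, genomes
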