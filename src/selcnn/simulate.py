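"""Site-class codon evolution with indels along a phylogeny.

The generator emulates the training conditions used throughout this package:
protein-coding genes evolve along a balanced 8-taxon tree under a codon
substitution model with three site classes,

* S0 — strong purifying selection, ``omega0 ~ U(0.1, 0.5)``,
* S1 — weak purifying selection,   ``omega1 ~ U(0.5, 0.9)``,
* S2 — the class whose ``omega2`` determines the gene label: purifying genes
  draw ``omega2 ~ U(0.9, 1.0)``, neutral genes fix ``omega2 = 1`` and
  positive-selection genes draw ``omega2 ~ U(1.5, 5)``,

occurring in proportions ``p0 ~ U(0.5, 0.8)``, ``p2 ~ U(0.01, 0.1)``,
``p1 = 1 - p0 - p2``.  The transition/transversion ratio ``kappa`` is drawn
from ``U(2, 3)`` and the root length (in codons) from a gamma distribution
with shape 4.2 and scale 85, rejection-sampled into [100, 600].

Substitution rates follow the standard codon-model form: for codons *i*, *j*
differing at one nucleotide, the unnormalized rate is
``pi_j * kappa^[transition] * omega_c^[nonsynonymous]``; other entries are
zero.  Rates are normalized per gene so that the site-class mixture has unit
expected substitutions per codon site per unit branch length, which makes
branch lengths directly interpretable as divergence.

Indels occur in whole-codon units (preserving reading frame) at a total rate
``r`` per codon site relative to the unit-mean substitution rate, split
between insertions and deletions by the configured ratio (1:1 by default,
``r = 0.1`` baseline).  Lengths are geometric over k >= 1 codons with
``P(k) = q (1-q)^(k-1)``, q = 0.35.  Evolution along each branch is an exact
event-level (Gillespie) simulation, so substitution/insertion/deletion event
counts are exact and the true alignment is recovered from a global column
registry that tracks homology across lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import codons
from .phylo import PhyloTree, TreeNode, build_symmetric_tree

GENE_CLASSES = ("purifying", "neutral", "positive")
SITE_CLASS_NAMES = ("S0", "S1", "S2")


# ---------------------------------------------------------------------------
# configuration and sampled per-gene parameters


@dataclass
class SimulationConfig:
    """Study conditions for dataset generation (defaults = baseline)."""

    n_taxa: int = 8
    divergence: float = 0.2  # expected substitutions / codon site / branch
    # gene-class mixture (fractions of genes, must sum to 1)
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {"purifying": 0.4, "neutral": 0.1, "positive": 0.5}
    )
    # root-length sampling: gamma(shape, scale) in codons, truncated
    root_length_shape: float = 4.2
    root_length_scale: float = 85.0
    root_length_min: int = 100
    root_length_max: int = 600
    # per-gene parameter ranges
    kappa_range: tuple[float, float] = (2.0, 3.0)
    omega0_range: tuple[float, float] = (0.1, 0.5)
    omega1_range: tuple[float, float] = (0.5, 0.9)
    omega2_purifying_range: tuple[float, float] = (0.9, 1.0)
    omega2_positive_range: tuple[float, float] = (1.5, 5.0)
    p0_range: tuple[float, float] = (0.5, 0.8)
    p2_range: tuple[float, float] = (0.01, 0.1)
    # indel process
    indel_rate: float = 0.1  # indel events per substitution
    insertion_deletion_ratio: float = 1.0
    indel_length_q: float = 0.35  # geometric success probability, codon units
    # stationary codon frequencies; None = equal over the 61 sense codons
    codon_frequencies: np.ndarray | None = None

    def frequencies(self) -> np.ndarray:
        if self.codon_frequencies is None:
            return np.full(codons.N_CODONS, 1.0 / codons.N_CODONS)
        return np.asarray(self.codon_frequencies, dtype=float)

    def tree(self) -> PhyloTree:
        return build_symmetric_tree(self.n_taxa, self.divergence)


@dataclass
class GeneProfile:
    """Evolutionary parameters sampled once per gene."""

    kappa: float
    omega0: float
    omega1: float
    omega2: float
    p0: float
    p1: float
    p2: float
    root_length: int
    gene_class: str  # purifying | neutral | positive

    @property
    def label(self) -> int:
        return 1 if self.gene_class == "positive" else 0

    @property
    def omegas(self) -> tuple[float, float, float]:
        return (self.omega0, self.omega1, self.omega2)

    @property
    def proportions(self) -> tuple[float, float, float]:
        return (self.p0, self.p1, self.p2)


@dataclass
class IndelModel:
    """Whole-codon indel process relative to the unit-mean substitution rate."""

    rate: float = 0.1  # total indel rate per codon site (r)
    insertion_deletion_ratio: float = 1.0
    length_q: float = 0.35  # geometric parameter, P(k) = q (1-q)^(k-1)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("indel rate must be >= 0")
        if not (0 < self.length_q <= 1):
            raise ValueError("geometric parameter q must lie in (0, 1]")
        if self.insertion_deletion_ratio < 0:
            raise ValueError("insertion:deletion ratio must be >= 0")

    @property
    def insertion_rate(self) -> float:
        f = self.insertion_deletion_ratio / (1.0 + self.insertion_deletion_ratio)
        return self.rate * f

    @property
    def deletion_rate(self) -> float:
        return self.rate - self.insertion_rate


@dataclass
class CodonModel:
    """Per-site-class scaled rate matrices sharing stationary frequencies."""

    frequencies: np.ndarray  # pi, length 61
    rate_matrices: np.ndarray  # shape (3, 61, 61), rows sum to 0, scaled
    scale: float  # nu: mixture expected rate before scaling


@dataclass
class EventCounts:
    substitutions: int = 0
    insertions: int = 0
    deletions: int = 0
    # lengths as drawn from the geometric distribution, before any
    # truncation at the sequence end (deletions only ever truncate)
    insertion_lengths: list[int] = field(default_factory=list)
    deletion_drawn_lengths: list[int] = field(default_factory=list)
    deletion_applied_lengths: list[int] = field(default_factory=list)

    @property
    def indels(self) -> int:
        return self.insertions + self.deletions


@dataclass
class GeneRecord:
    """One simulated gene: sequences, true alignment and annotation."""

    gene_id: str
    profile: GeneProfile
    leaf_names: list[str]
    leaf_sequences: dict[str, str]  # unaligned codon strings per taxon
    alignment_rows: list[tuple[str, str]]  # (taxon, gapped nt string)
    column_classes: np.ndarray  # site class (0/1/2) per codon column
    column_inserted: np.ndarray  # bool per codon column
    events: EventCounts
    branch_codon_sites: float = 0.0  # sum over branches of codon sites present

    @property
    def label(self) -> int:
        return self.profile.label

    @property
    def alignment_length(self) -> int:
        return len(self.alignment_rows[0][1]) if self.alignment_rows else 0


# ---------------------------------------------------------------------------
# parameter sampling


def sample_gene_profile(
    config: SimulationConfig, gene_class: str, rng: np.random.Generator
) -> GeneProfile:
    """Draw one gene's parameters from the configured distributions."""
    if gene_class not in GENE_CLASSES:
        raise ValueError(f"unknown gene class {gene_class!r}")

    kappa = rng.uniform(*config.kappa_range)
    omega0 = rng.uniform(*config.omega0_range)
    omega1 = rng.uniform(*config.omega1_range)
    if gene_class == "purifying":
        omega2 = rng.uniform(*config.omega2_purifying_range)
    elif gene_class == "neutral":
        omega2 = 1.0
    else:
        omega2 = rng.uniform(*config.omega2_positive_range)

    p0 = rng.uniform(*config.p0_range)
    p2 = rng.uniform(*config.p2_range)
    p1 = 1.0 - p0 - p2

    lo, hi = config.root_length_min, config.root_length_max
    while True:
        length = int(
            round(rng.gamma(config.root_length_shape, config.root_length_scale))
        )
        if lo <= length <= hi:
            break

    return GeneProfile(
        kappa=kappa,
        omega0=omega0,
        omega1=omega1,
        omega2=omega2,
        p0=p0,
        p1=p1,
        p2=p2,
        root_length=length,
        gene_class=gene_class,
    )


def build_codon_model(
    profile: GeneProfile, frequencies: np.ndarray | None = None
) -> CodonModel:
    """Assemble the three per-class rate matrices with mixture normalization.

    The unnormalized rate from codon i to codon j (single-nucleotide
    neighbours only, stop codons excluded by construction) is
    ``pi_j * kappa^[transition] * omega_c^[nonsynonymous]``.  All three
    matrices are divided by ``nu = sum_c p_c sum_i pi_i (-Q_c[i,i])`` so the
    site-class mixture evolves at one expected substitution per codon site per
    unit branch length.
    """
    if frequencies is None:
        pi = np.full(codons.N_CODONS, 1.0 / codons.N_CODONS)
    else:
        pi = np.asarray(frequencies, dtype=float)
    if pi.shape != (codons.N_CODONS,):
        raise ValueError(f"frequencies must have length {codons.N_CODONS}")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1 (tolerance 1e-9)")
    if np.any(pi <= 0):
        raise ValueError("frequencies must all be positive")

    base = np.where(codons.SINGLE_CHANGE, pi[np.newaxis, :], 0.0)
    base = np.where(codons.IS_TRANSITION, base * profile.kappa, base)

    qs = np.empty((3, codons.N_CODONS, codons.N_CODONS))
    for c, omega in enumerate(profile.omegas):
        q = np.where(
            codons.SINGLE_CHANGE & ~codons.IS_SYNONYMOUS, base * omega, base
        )
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        qs[c] = q

    weights = np.asarray(profile.proportions)
    nu = float(np.sum(weights[:, None] * (pi * -np.diagonal(qs, axis1=1, axis2=2))))
    qs /= nu
    return CodonModel(frequencies=pi, rate_matrices=qs, scale=nu)


# ---------------------------------------------------------------------------
# Gillespie machinery


class _Kernel:
    """Sampling tables derived from a CodonModel for fast event simulation."""

    def __init__(self, model: CodonModel):
        q = model.rate_matrices
        self.exit_rates = -np.diagonal(q, axis1=1, axis2=2).copy()  # (3, 61)
        trans = q.copy()
        for c in range(trans.shape[0]):
            np.fill_diagonal(trans[c], 0.0)
        trans /= self.exit_rates[:, :, None]
        self.cum_trans = np.cumsum(trans, axis=2)  # (3, 61, 61)
        self.cum_pi = np.cumsum(model.frequencies)


class _ColumnRegistry:
    """Global homology bookkeeping: every column ever created, in MSA order."""

    def __init__(self) -> None:
        self.order: list[int] = []
        self.site_class: list[int] = []
        self.inserted: list[bool] = []
        self._next = 0

    def new_root_columns(self, classes: np.ndarray) -> np.ndarray:
        ids = np.arange(self._next, self._next + len(classes))
        self._next += len(classes)
        self.order.extend(ids.tolist())
        self.site_class.extend(int(c) for c in classes)
        self.inserted.extend([False] * len(classes))
        return ids

    def new_inserted_columns(
        self, classes: np.ndarray, after: int | None, before: int | None
    ) -> np.ndarray:
        ids = np.arange(self._next, self._next + len(classes))
        self._next += len(classes)
        if after is not None:
            pos = self.order.index(after) + 1
        elif before is not None:
            pos = self.order.index(before)
        else:
            pos = len(self.order)
        self.order[pos:pos] = ids.tolist()
        for k, c in enumerate(classes):
            self.site_class.insert(pos + k, int(c))
            self.inserted.insert(pos + k, True)
        return ids


def _sample_indices(cum: np.ndarray, rng: np.random.Generator, size: int) -> np.ndarray:
    u = rng.random(size) * cum[-1]
    return np.searchsorted(cum, u, side="right")


def _evolve_branch(
    states: np.ndarray,
    cols: np.ndarray,
    classes: np.ndarray,
    branch_length: float,
    kernel: _Kernel,
    indel: IndelModel,
    cum_class: np.ndarray,
    registry: _ColumnRegistry,
    rng: np.random.Generator,
    counts: EventCounts,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact event-level simulation of one branch; returns the child arrays."""
    t_remaining = branch_length
    ins_rate = indel.insertion_rate
    del_rate = indel.deletion_rate

    while True:
        n_sites = len(states)
        if n_sites == 0:
            break  # lineage lost all sites; nothing left to evolve
        site_rates = kernel.exit_rates[classes, states]
        total_sub = float(site_rates.sum())
        total_ins = ins_rate * n_sites
        total_del = del_rate * n_sites
        total = total_sub + total_ins + total_del
        t_remaining -= rng.exponential() / total
        if t_remaining <= 0:
            break
        u = rng.random() * total
        if u < total_sub:
            cum = np.cumsum(site_rates)
            site = int(np.searchsorted(cum, u, side="right"))
            site = min(site, n_sites - 1)
            row = kernel.cum_trans[classes[site], states[site]]
            states[site] = int(
                np.searchsorted(row, rng.random() * row[-1], side="right")
            )
            counts.substitutions += 1
        elif u < total_sub + total_ins:
            slot = int(rng.integers(n_sites + 1))
            k = int(rng.geometric(indel.length_q))
            new_states = _sample_indices(kernel.cum_pi, rng, k)
            new_classes = _sample_indices(cum_class, rng, k)
            after = int(cols[slot - 1]) if slot > 0 else None
            before = int(cols[slot]) if slot < n_sites else None
            new_cols = registry.new_inserted_columns(
                new_classes, after=after, before=before if after is None else None
            )
            states = np.concatenate([states[:slot], new_states, states[slot:]])
            classes = np.concatenate([classes[:slot], new_classes, classes[slot:]])
            cols = np.concatenate([cols[:slot], new_cols, cols[slot:]])
            counts.insertions += 1
            counts.insertion_lengths.append(k)
        else:
            start = int(rng.integers(n_sites))
            drawn = int(rng.geometric(indel.length_q))
            k = min(drawn, n_sites - start)
            keep = np.ones(n_sites, dtype=bool)
            keep[start : start + k] = False
            states, classes, cols = states[keep], classes[keep], cols[keep]
            counts.deletions += 1
            counts.deletion_drawn_lengths.append(drawn)
            counts.deletion_applied_lengths.append(k)

    return states, cols, classes


def simulate_gene(
    profile: GeneProfile,
    tree: PhyloTree,
    codon_model: CodonModel,
    indel_model: IndelModel,
    rng: np.random.Generator,
    gene_id: str = "gene",
) -> GeneRecord:
    """Evolve one gene along the tree and emit its true alignment.

    The root sequence is drawn site-wise from the stationary frequencies with
    site classes assigned i.i.d. from (p0, p1, p2); each branch is then run as
    an exact event-level simulation (see module docstring).  Inserted codons
    draw their state from the stationary frequencies and their site class
    from (p0, p1, p2).
    """
    if tree.n_leaves < 2:
        raise ValueError("tree must have at least 2 leaves")
    kernel = _Kernel(codon_model)
    cum_class = np.cumsum(np.asarray(profile.proportions))
    registry = _ColumnRegistry()
    counts = EventCounts()

    root_classes = _sample_indices(cum_class, rng, profile.root_length)
    root_states = _sample_indices(kernel.cum_pi, rng, profile.root_length)
    root_cols = registry.new_root_columns(root_classes)

    leaf_data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    branch_sites = 0.0

    def walk(node: TreeNode, states: np.ndarray, cols: np.ndarray, classes: np.ndarray) -> None:
        nonlocal branch_sites
        for child in node.children:
            branch_sites += len(states)
            s, co, cl = _evolve_branch(
                states.copy(),
                cols.copy(),
                classes.copy(),
                child.branch_length,
                kernel,
                indel_model,
                cum_class,
                registry,
                rng,
                counts,
            )
            if child.is_leaf:
                leaf_data[child.name] = (s, co)
            else:
                walk(child, s, co, cl)

    walk(tree.root, root_states, root_cols, root_classes)

    leaf_names = tree.leaf_names
    maps = {
        name: dict(zip(cols.tolist(), states.tolist()))
        for name, (states, cols) in leaf_data.items()
    }

    kept_cols = [c for c in registry.order if any(c in m for m in maps.values())]
    col_pos = {c: i for i, c in enumerate(registry.order)}
    column_classes = np.array(
        [registry.site_class[col_pos[c]] for c in kept_cols], dtype=np.int8
    )
    column_inserted = np.array(
        [registry.inserted[col_pos[c]] for c in kept_cols], dtype=bool
    )

    alignment_rows = []
    leaf_sequences = {}
    for name in leaf_names:
        m = maps[name]
        row = "".join(
            codons.SENSE_CODONS[m[c]] if c in m else "---" for c in kept_cols
        )
        alignment_rows.append((name, row))
        leaf_sequences[name] = row.replace("-", "")

    return GeneRecord(
        gene_id=gene_id,
        profile=profile,
        leaf_names=leaf_names,
        leaf_sequences=leaf_sequences,
        alignment_rows=alignment_rows,
        column_classes=column_classes,
        column_inserted=column_inserted,
        events=counts,
        branch_codon_sites=branch_sites,
    )


# ---------------------------------------------------------------------------
# dataset-level generation


def allocate_classes(proportions: dict[str, float], n_genes: int) -> list[str]:
    """Deterministically interleave gene classes to match proportions exactly.

    Quotas are assigned by largest remainder (ties and leftover to the
    largest class); genes are then scheduled by maximum remaining deficit so
    classes interleave rather than run in blocks.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    classes = list(proportions)
    fracs = np.array([proportions[c] for c in classes], dtype=float)
    if np.any(fracs < 0) or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must be >= 0 and sum to 1")

    exact = fracs * n_genes
    quotas = np.floor(exact).astype(int)
    remainder = int(n_genes - quotas.sum())
    by_size = sorted(
        range(len(classes)), key=lambda i: (-(exact[i] - quotas[i]), -fracs[i], i)
    )
    for i in range(remainder):
        quotas[by_size[i % len(classes)]] += 1

    assigned = np.zeros(len(classes), dtype=int)
    out: list[str] = []
    for g in range(n_genes):
        deficit = quotas * (g + 1) / n_genes - assigned
        deficit[assigned >= quotas] = -np.inf
        pick = int(np.argmax(deficit))
        assigned[pick] += 1
        out.append(classes[pick])
    return out


@dataclass
class ManifestRow:
    gene_id: str
    gene_class: str
    label: int
    profile: GeneProfile
    seed_key: int


def plan_dataset(
    config: SimulationConfig, n_genes: int, seed: int
) -> list[ManifestRow]:
    """Sample every gene's class and parameters without evolving sequences."""
    rows = []
    for index, gene_class in enumerate(allocate_classes(config.class_proportions, n_genes)):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))
        profile = sample_gene_profile(config, gene_class, rng)
        rows.append(
            ManifestRow(
                gene_id=f"gene{index:05d}",
                gene_class=gene_class,
                label=profile.label,
                profile=profile,
                seed_key=index,
            )
        )
    return rows


def gene_rng(seed: int, index: int) -> np.random.Generator:
    """Independent, order-free random substream for gene ``index``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def simulate_dataset(config: SimulationConfig, n_genes: int, seed: int):
    """Yield GeneRecords for a dataset with exact class proportions.

    Each gene consumes an independent substream derived from ``seed`` and its
    index, so regeneration of any single gene is reproducible in isolation.
    """
    tree = config.tree()
    indel = IndelModel(
        rate=config.indel_rate,
        insertion_deletion_ratio=config.insertion_deletion_ratio,
        length_q=config.indel_length_q,
    )
    pi = config.frequencies()
    for index, gene_class in enumerate(allocate_classes(config.class_proportions, n_genes)):
        rng = gene_rng(seed, index)
        profile = sample_gene_profile(config, gene_class, rng)
        model = build_codon_model(profile, pi)
        yield simulate_gene(
            profile, tree, model, indel, rng, gene_id=f"gene{index:05d}"
        )


def write_dataset(
    config: SimulationConfig, n_genes: int, seed: int, out_dir
) -> list[GeneRecord]:
    """Simulate a dataset and write it as a directory of plain-text files.

    Layout: ``unaligned/{gene_id}.fasta``, ``true_alignment/{gene_id}.fasta``,
    ``annotations/{gene_id}.tsv`` (0-based codon column, site class, omega,
    inserted flag), ``tree.nwk`` and ``manifest.tsv``.
    """
    from pathlib import Path

    from .seqio import write_fasta

    out = Path(out_dir)
    for sub in ("unaligned", "true_alignment", "annotations"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(config.tree().to_newick() + "\n")

    records = []
    for rec in simulate_dataset(config, n_genes, seed):
        records.append(rec)
        write_fasta(
            [(name, rec.leaf_sequences[name]) for name in rec.leaf_names],
            out / "unaligned" / f"{rec.gene_id}.fasta",
        )
        write_fasta(rec.alignment_rows, out / "true_alignment" / f"{rec.gene_id}.fasta")
        omegas = rec.profile.omegas
        with open(out / "annotations" / f"{rec.gene_id}.tsv", "w") as fh:
            fh.write("codon_column\tsite_class\tomega\tinserted\n")
            for i, (cls, ins) in enumerate(
                zip(rec.column_classes.tolist(), rec.column_inserted.tolist())
            ):
                fh.write(
                    f"{i}\t{SITE_CLASS_NAMES[cls]}\t{omegas[cls]:.6g}\t{int(ins)}\n"
                )
    manifest_frame(records, seed).to_csv(out / "manifest.tsv", sep="\t", index=False)
    return records


def read_annotation_classes(path) -> np.ndarray:
    """Site classes (0/1/2 per codon column) from an annotations TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return df["site_class"].map({n: i for i, n in enumerate(SITE_CLASS_NAMES)}).to_numpy()


def manifest_frame(records: list[GeneRecord], seed: int):
    """Tabular manifest (pandas DataFrame) for a simulated dataset."""
    import pandas as pd

    rows = []
    for index, rec in enumerate(records):
        p = rec.profile
        rows.append(
            {
                "gene_id": rec.gene_id,
                "gene_class": p.gene_class,
                "label": p.label,
                "kappa": p.kappa,
                "omega0": p.omega0,
                "omega1": p.omega1,
                "omega2": p.omega2,
                "p0": p.p0,
                "p1": p.p1,
                "p2": p.p2,
                "root_length": p.root_length,
                "substitutions": rec.events.substitutions,
                "insertions": rec.events.insertions,
                "deletions": rec.events.deletions,
                "seed": seed,
                "seed_key": index,
            }
        )
    return pd.DataFrame(rows)
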