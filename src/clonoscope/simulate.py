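"""Synthetic data with known ground truth for the clonal-analysis pipeline.

Emulates the statistical structure of a joint CRISPR-perturbation +
lineage-barcode single-cell experiment in the embryonic ganglionic
eminences: clones of mixed cell classes (mitotic progenitors, GABAergic
projection neurons, MGE- and CGE-derived interneurons), a
perturbation-induced shift of probability mass from the PN class to the IN
classes, batch structure, barcode sequencing reads with substitution
errors, and an expression matrix with class-informative marker genes.

Every generator is a pure function of its configuration: one root seed,
with independent child streams derived per component by a fixed counter
(``default_rng([seed, stream])``), so reruns are bitwise identical and
components can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layout import DEFAULT_LAYOUT, BarcodeLayout, ReadStructure

CLASSES = ("mitotic", "PN", "IN-MGE", "IN-CGE")

# child RNG stream ids (counter scheme: default_rng([seed, stream]))
_STREAM_LIBRARY = 0
_STREAM_CLONES = 1
_STREAM_FASTQ = 2
_STREAM_EXPRESSION = 3
_STREAM_STATES = 4

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe a two-arm (control guide vs perturbing guide),
    two-batch electroporation experiment with sparse clonal labeling.
    """

    n_progenitors: int = 150  # clones per batch per arm
    clone_size_law: dict = field(
        default_factory=lambda: {1: 0.45, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.05}
    )
    class_probs_control: dict = field(
        default_factory=lambda: {"mitotic": 0.20, "PN": 0.50, "IN-MGE": 0.15, "IN-CGE": 0.15}
    )
    #: probability mass moved from PN to the IN classes in the perturbed arm
    fate_shift_delta: float = 0.15
    #: how the shifted mass splits between IN-MGE and IN-CGE
    fate_shift_split: tuple = (0.5, 0.5)
    n_batches: int = 2
    arm_labels: tuple = ("gLacZ", "gMeis2")
    bridge_layout: BarcodeLayout = DEFAULT_LAYOUT
    read_structure: ReadStructure = ReadStructure()
    per_base_error: float = 0.005
    reads_per_cell: int = 20
    umis_per_barcode: int = 5
    quality_model: tuple = (36.0, 4.0)  # mean/sd of per-base Phred
    n_genes: int = 3000
    n_informative_genes: int = 50
    informative_log2fc: float = 2.0
    #: optional clone-level coupling: (state_a, state_b, enrichment_factor)
    coupling: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        validate_probs(self.clone_size_law, "clone_size_law")
        validate_probs(self.class_probs_control, "class_probs_control")
        if set(self.class_probs_control) != set(CLASSES):
            raise ValueError(f"class_probs_control must cover exactly {CLASSES}")
        if any(s < 1 for s in self.clone_size_law):
            raise ValueError("clone sizes must be >= 1")
        d = self.fate_shift_delta
        if not 0.0 <= d <= self.class_probs_control["PN"]:
            raise ValueError(
                f"fate_shift_delta must lie in [0, P(PN)={self.class_probs_control['PN']}], got {d}"
            )
        if abs(sum(self.fate_shift_split) - 1.0) > 1e-12:
            raise ValueError("fate_shift_split must sum to 1")
        if len(self.arm_labels) != 2:
            raise ValueError("arm_labels must name exactly two arms (control, perturbed)")
        if not 0.0 <= self.per_base_error < 1.0:
            raise ValueError("per_base_error must be in [0, 1)")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes cannot exceed n_genes")

    @property
    def barcode_length(self) -> int:
        return self.bridge_layout.length

    def class_probs(self, arm: str) -> dict:
        """Class probabilities in ``arm`` (perturbed arm has the PN→IN shift)."""
        if arm == self.arm_labels[0]:
            return dict(self.class_probs_control)
        if arm == self.arm_labels[1]:
            d = self.fate_shift_delta
            p = dict(self.class_probs_control)
            p["PN"] -= d
            p["IN-MGE"] += d * self.fate_shift_split[0]
            p["IN-CGE"] += d * self.fate_shift_split[1]
            return p
        raise ValueError(f"unknown arm {arm!r}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside each simulated dataset."""

    clone_of: dict  # cell_id -> true clone id
    class_of: dict  # cell_id -> true class
    fate_shift_delta: float
    informative_genes: list = field(default_factory=list)  # (gene_id, signed log2fc)
    coupling: list = field(default_factory=list)  # (state_a, state_b, factor)


def validate_probs(probs: dict, name: str) -> None:
    vals = np.asarray(list(probs.values()), dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError(f"{name}: probabilities must lie in [0, 1]")
    if abs(vals.sum() - 1.0) > 1e-12:
        raise ValueError(f"{name}: probabilities must sum to 1 (got {vals.sum()!r})")


# ---------------------------------------------------------------------------
# barcode library


def generate_barcode_library(
    n: int,
    layout: BarcodeLayout = DEFAULT_LAYOUT,
    min_pairwise_hamming: int = 7,
    seed: int = 0,
    max_rejections: int = 10_000,
) -> list[str]:
    """Draw ``n`` distinct barcodes whose random positions are mutually
    separated by at least ``min_pairwise_hamming`` substitutions.

    The default separation of 7 (= 2·3 + 1) guarantees that single-linkage
    clustering at Hamming distance 3 can never merge reads derived from two
    different library barcodes.  Sampling is rejection-based and
    deterministic in ``seed``; an unsatisfiable request fails after
    ``max_rejections`` consecutive rejections rather than looping forever.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    n_random = len(layout.random_positions)
    if min_pairwise_hamming < 0:
        raise ValueError("min_pairwise_hamming must be >= 0")
    if n > 1 and min_pairwise_hamming > n_random:
        raise ValueError(
            f"min_pairwise_hamming={min_pairwise_hamming} exceeds the "
            f"{n_random} random positions; unsatisfiable"
        )
    rng = _rng(seed, _STREAM_LIBRARY)
    accepted = np.empty((0, n_random), dtype=np.uint8)
    rejections = 0
    while accepted.shape[0] < n:
        cand = rng.integers(0, 4, size=n_random, dtype=np.uint8)
        if accepted.shape[0] == 0 or (accepted != cand).sum(axis=1).min() >= min_pairwise_hamming:
            accepted = np.vstack([accepted, cand])
            rejections = 0
        else:
            rejections += 1
            if rejections >= max_rejections:
                raise RuntimeError(
                    f"could not place barcode {accepted.shape[0] + 1}/{n} at "
                    f"min Hamming {min_pairwise_hamming} after {max_rejections} rejections"
                )
    return [layout.render("".join("ACGT"[b] for b in row)) for row in accepted]


# ---------------------------------------------------------------------------
# clones


def simulate_clones(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a clone table: one row per cell with clone, class, arm, batch.

    Per batch and arm, ``n_progenitors`` progenitors each found one clone;
    clone sizes follow ``clone_size_law`` and each cell's class is drawn
    from the arm's class probabilities (the perturbed arm's probabilities
    carry the PN→IN shift, so fate switching acts on whole newly generated
    clones).  Optional ``coupling`` entries bias clones to span a state
    pair at roughly ``factor`` times the independence rate.
    """
    rng = _rng(config.seed, _STREAM_CLONES)
    sizes_support = np.array(sorted(config.clone_size_law), dtype=int)
    sizes_probs = np.array([config.clone_size_law[s] for s in sizes_support], dtype=float)

    rows: list[tuple] = []
    cell_counter = 0
    for batch_idx in range(config.n_batches):
        batch = f"batch{batch_idx + 1}"
        for arm in config.arm_labels:
            probs = config.class_probs(arm)
            class_names = list(probs)
            class_p = np.array([probs[c] for c in class_names], dtype=float)
            force_p = _coupling_force_probs(config, probs, sizes_support, sizes_probs)
            for clone_idx in range(config.n_progenitors):
                clone = f"{batch}:{arm}:c{clone_idx:04d}"
                size = int(rng.choice(sizes_support, p=sizes_probs))
                classes = [class_names[i] for i in rng.choice(len(class_names), size=size, p=class_p)]
                for (a, b, _f), pf in zip(config.coupling, force_p):
                    if size >= 2 and rng.random() < pf and not ({a, b} <= set(classes)):
                        i, j = rng.choice(size, size=2, replace=False)
                        classes[int(i)], classes[int(j)] = a, b
                for cls in classes:
                    rows.append((f"cell{cell_counter:06d}", clone, cls, arm, batch))
                    cell_counter += 1

    table = pd.DataFrame(rows, columns=["cell_id", "clone_id", "cell_class", "arm", "batch"])
    truth = SimTruth(
        clone_of=dict(zip(table["cell_id"], table["clone_id"])),
        class_of=dict(zip(table["cell_id"], table["cell_class"])),
        fate_shift_delta=config.fate_shift_delta,
        coupling=list(config.coupling),
    )
    return table, truth


def _coupling_force_probs(config, probs, sizes_support, sizes_probs) -> list[float]:
    """Per coupled pair, the probability of forcing co-occurrence in a clone.

    Uses the analytic per-clone presence probability of each state under the
    size law, p_s = E[1 - (1 - prob_s)^size], and forces at rate
    (factor - 1) * p_a * p_b so co-occurrence lands near factor times the
    independence rate.
    """
    out = []
    for a, b, factor in config.coupling:
        pa = float(np.sum(sizes_probs * (1 - (1 - probs[a]) ** sizes_support)))
        pb = float(np.sum(sizes_probs * (1 - (1 - probs[b]) ** sizes_support)))
        out.append(min(1.0, max(0.0, (factor - 1.0) * pa * pb)))
    return out


def simulate_multistate_clones(
    n_clones: int,
    states: tuple = ("A", "B", "C"),
    state_probs: tuple | None = None,
    size_law: dict | None = None,
    arm: str = "arm1",
    batch: str = "batch1",
    seed: int = 0,
) -> pd.DataFrame:
    """Clones whose cells draw their state iid from ``state_probs``.

    The fully independent per-cell assignment: no lineage coupling of any
    kind, so shared-state structure arises only from clone sizes and the
    state frequencies.  ``size_law`` maps clone size → probability
    (default: uniform over 12..25 cells, i.e. well-sampled clones for
    which every state is usually represented).
    """
    if state_probs is None:
        state_probs = tuple(1.0 / len(states) for _ in states)
    validate_probs(dict(zip(states, state_probs)), "state_probs")
    if size_law is None:
        size_law = {s: 1.0 / 14 for s in range(12, 26)}
    validate_probs(size_law, "size_law")
    sizes_support = np.array(sorted(size_law), dtype=int)
    sizes_probs = np.array([size_law[s] for s in sizes_support], dtype=float)
    rng = _rng(seed, _STREAM_STATES)
    rows = []
    for k in range(n_clones):
        clone = f"{batch}:{arm}:c{k:05d}"
        size = int(rng.choice(sizes_support, p=sizes_probs))
        cells = rng.choice(len(states), size=size, p=np.asarray(state_probs, dtype=float))
        for i, s_ix in enumerate(cells):
            rows.append((f"{clone}:cell{i}", clone, states[s_ix], arm, batch))
    return pd.DataFrame(rows, columns=["cell_id", "clone_id", "cell_class", "arm", "batch"])


def simulate_clone_states(
    n_clones: int,
    states: tuple = ("A", "B", "C"),
    presence_prob: float = 0.5,
    coupled_pairs: tuple = (),
    arm: str = "arm1",
    batch: str = "batch1",
    seed: int = 0,
) -> pd.DataFrame:
    """Directly simulate clone→state incidence with exact marginals.

    Each clone contains each state independently with ``presence_prob``.
    For a ``(state_a, state_b, factor)`` entry, the joint presence
    probability is set to ``factor * presence_prob**2`` while both
    marginals stay at ``presence_prob`` (a three-cell mixture:
    both / a-only / b-only), so co-occurrence is *exactly* ``factor``
    times the independence rate.  One cell is emitted per (clone, state).
    """
    coupled = {}
    for a, b, factor in coupled_pairs:
        q = factor * presence_prob**2
        if q > min(presence_prob, presence_prob):
            raise ValueError(f"factor {factor} with presence_prob {presence_prob} is infeasible")
        coupled[frozenset((a, b))] = q
    flat = [s for pair in coupled for s in pair]
    if len(flat) != len(set(flat)):
        raise ValueError("a state may appear in at most one coupled pair")

    rng = _rng(seed, _STREAM_STATES)
    rows = []
    for k in range(n_clones):
        clone = f"{batch}:{arm}:c{k:05d}"
        members: list[str] = []
        handled = set()
        for pair, q in coupled.items():
            a, b = sorted(pair)
            u = rng.random()
            if u < q:
                members += [a, b]
            elif u < presence_prob:  # a-only mass: presence_prob - q
                members.append(a)
            elif u < 2 * presence_prob - q:  # b-only mass
                members.append(b)
            handled |= pair
        for s in states:
            if s not in handled and rng.random() < presence_prob:
                members.append(s)
        for i, s in enumerate(members):
            rows.append((f"{clone}:cell{i}", clone, s, arm, batch))
    return pd.DataFrame(rows, columns=["cell_id", "clone_id", "cell_class", "arm", "batch"])


# ---------------------------------------------------------------------------
# reads


def synthesize_fastq(
    clone_table: pd.DataFrame,
    barcodes: list[str],
    config: SimConfig,
) -> tuple[list, pd.DataFrame]:
    """Simulate barcode-carrying reads for every cell in ``clone_table``.

    Each clone is tied to one library barcode (``barcodes`` indexed by the
    clone's order of first appearance, per batch so distinct batches reuse
    the library independently).  Every cell yields ``reads_per_cell`` reads:
    5' anchor + barcode with iid per-base substitution errors + 3' anchor,
    with Phred qualities drawn from ``quality_model`` (clipped to [2, 41]).
    UMIs are drawn per read from the cell's pool of ``umis_per_barcode``
    distinct 10-mers, so PCR-jackpot duplicates exist by construction.

    Returns ``(reads, truth_map)``: reads as :class:`~clonoscope.barcode.ReadRecord`
    and a per-read table linking read id to cell, clone and the error-free
    library barcode.
    """
    from .barcode import ReadRecord  # local import to avoid a cycle

    clones = list(dict.fromkeys(clone_table["clone_id"]))
    if len(barcodes) < len(clones):
        raise ValueError(f"need >= {len(clones)} library barcodes, got {len(barcodes)}")
    barcode_of = dict(zip(clones, barcodes))

    rng = _rng(config.seed, _STREAM_FASTQ)
    rs = config.read_structure
    qmean, qsd = config.quality_model
    reads: list[ReadRecord] = []
    truth_rows = []
    read_counter = 0
    for cell_id, clone_id in zip(clone_table["cell_id"], clone_table["clone_id"]):
        true_bc = barcode_of[clone_id]
        bc_arr = np.frombuffer(true_bc.encode(), dtype="S1").copy()
        umi_pool = ["".join("ACGT"[b] for b in rng.integers(0, 4, size=10)) for _ in range(config.umis_per_barcode)]
        for _ in range(config.reads_per_cell):
            bc = bc_arr.copy()
            if config.per_base_error > 0:
                hit = rng.random(len(bc)) < config.per_base_error
                if hit.any():
                    # substitute with a uniformly chosen *different* base
                    shift = rng.integers(1, 4, size=int(hit.sum()))
                    idx = np.nonzero(hit)[0]
                    cur = np.searchsorted(_BASES, bc[idx])
                    bc[idx] = _BASES[(cur + shift) % 4]
            seq = rs.anchor5 + bc.tobytes().decode() + rs.anchor3
            quals = np.clip(np.rint(rng.normal(qmean, qsd, size=len(seq))), 2, 41).astype(int)
            read_id = f"read{read_counter:08d}"
            read_counter += 1
            umi = umi_pool[int(rng.integers(0, len(umi_pool)))]
            reads.append(ReadRecord(read_id=read_id, sequence=seq, qualities=quals.tolist(), cell_id=cell_id, umi=umi))
            truth_rows.append((read_id, cell_id, clone_id, true_bc))

    truth_map = pd.DataFrame(truth_rows, columns=["read_id", "cell_id", "clone_id", "true_barcode"])
    return reads, truth_map


# ---------------------------------------------------------------------------
# expression


def simulate_expression(clone_table: pd.DataFrame, config: SimConfig):
    """Simulate a cell×gene count matrix with class-informative genes.

    Counts are gamma–Poisson (negative binomial, dispersion 1/10).
    Non-informative genes share one mean across classes; each informative
    gene g has a signed log2 fold change s_g between PN and IN cells
    (PN mean = base·2^{s/2}, IN mean = base·2^{-s/2}); mitotic cells sit at
    the base mean.  The first half of informative genes are PN-up, the
    second half IN-up.

    Returns an :class:`anndata.AnnData` (cells × genes, integer counts)
    whose ``.obs`` carries the clone table and whose ``.var`` carries the
    per-gene truth, plus the list of (gene, signed log2fc) effects.
    """
    import anndata as ad

    rng = _rng(config.seed, _STREAM_EXPRESSION)
    n_cells = len(clone_table)
    genes = [f"gene{i:04d}" for i in range(config.n_genes)]
    base_mean = rng.lognormal(mean=0.7, sigma=0.8, size=config.n_genes)

    signed_lfc = np.zeros(config.n_genes)
    n_inf = config.n_informative_genes
    signed_lfc[: n_inf // 2] = config.informative_log2fc
    signed_lfc[n_inf // 2 : n_inf] = -config.informative_log2fc

    classes = clone_table["cell_class"].to_numpy()
    is_pn = classes == "PN"
    is_in = np.isin(classes, ["IN-MGE", "IN-CGE"])

    # cells × genes mean matrix via class multipliers on informative genes
    mult = np.ones((n_cells, config.n_genes))
    mult[np.ix_(is_pn, np.arange(n_inf))] = 2.0 ** (signed_lfc[:n_inf] / 2.0)
    mult[np.ix_(is_in, np.arange(n_inf))] = 2.0 ** (-signed_lfc[:n_inf] / 2.0)
    mu = mult * base_mean[None, :]

    theta = 10.0  # gamma-Poisson shape: var = mu + mu^2/theta
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int32)

    obs = clone_table.set_index("cell_id").copy()
    obs.index.name = None
    var = pd.DataFrame(
        {"informative": signed_lfc != 0, "signed_log2fc": signed_lfc, "base_mean": base_mean},
        index=genes,
    )
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    truth = [(g, float(s)) for g, s in zip(genes, signed_lfc) if s != 0]
    return adata, truth


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: clones + barcode library + reads + expression."""
    clone_table, truth = simulate_clones(config)
    n_clones = clone_table["clone_id"].nunique()
    library = generate_barcode_library(n_clones, config.bridge_layout, seed=config.seed)
    reads, truth_map = synthesize_fastq(clone_table, library, config)
    adata, gene_truth = simulate_expression(clone_table, config)
    truth.informative_genes = gene_truth
    return {
        "clone_table": clone_table,
        "truth": truth,
        "library": library,
        "reads": reads,
        "read_truth": truth_map,
        "expression": adata,
    }
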