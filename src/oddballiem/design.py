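"""Counterbalanced stimulus-sequence construction for roving-oddball designs.

Builds the orientation sequences used by oddball EEG experiments: modified de
Bruijn sequences that balance transition statistics, roving-standard blocks
(trains of repeated orientations ending in a deviant), equiprobable control
blocks (a new orientation on every presentation), target placement, and the
condition labelling (deviant / standard / control) plus the signed mismatch
angle that downstream decoding consumes.

Orientations live on a 180-degree circular space sampled at ``orientation_step``
(default 20 deg, nine orientations 0..160). Event tables are plain pandas
DataFrames; see :data:`EVENT_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SequenceConfig",
    "EVENT_COLUMNS",
    "generate_pair_debruijn",
    "generate_triple_debruijn",
    "build_master_sequence",
    "build_roving_blocks",
    "build_equiprobable_blocks",
    "place_targets",
    "label_conditions",
    "wrap_mismatch",
    "simulate_design",
]

#: Columns of a fully labelled event table, in serialization order.
EVENT_COLUMNS = [
    "block",
    "onset_s",
    "orientation_deg",
    "sequence_type",
    "condition",
    "attention",
    "train_position",
    "train_length",
    "mismatch_deg",
    "n_preceding_standards",
    "is_target",
]


@dataclass
class SequenceConfig:
    """Parameters of the stimulus sequence.

    Defaults reproduce the roving-oddball design: nine orientations in 20-deg
    steps, 415 gratings per block (100 ms on, 500 ms ISI), 18 roving and 3
    equiprobable blocks, train lengths 4..11 drawn with relative weights
    (31, 31, 31, 23, 5, 5, 5, 5), 18 spatial-frequency targets per block
    (2 per orientation, >= 1.5 s apart) and 18 fixation-dot events per block.
    """

    n_orientations: int = 9
    orientation_step: float = 20.0
    gratings_per_block: int = 415
    n_roving_blocks: int = 18
    n_equiprobable_blocks: int = 3
    train_length_support: tuple = tuple(range(4, 12))
    train_length_weights: tuple = (31, 31, 31, 23, 5, 5, 5, 5)
    targets_per_block: int = 18
    min_target_gap: float = 1.5
    stimulus_duration: float = 0.1
    isi: float = 0.5
    dot_events_per_block: int = 18
    standard_window: tuple = (5, 7)

    def __post_init__(self):
        if self.n_orientations * self.orientation_step != 180:
            raise ValueError("n_orientations * orientation_step must equal 180")
        if len(self.train_length_weights) != len(self.train_length_support):
            raise ValueError("one train-length weight per support element required")
        if self.targets_per_block % self.n_orientations != 0:
            raise ValueError("targets_per_block must be divisible by n_orientations")

    @property
    def orientations(self) -> np.ndarray:
        return np.arange(self.n_orientations) * self.orientation_step

    @property
    def soa(self) -> float:
        """Stimulus-onset asynchrony (duration + ISI)."""
        return self.stimulus_duration + self.isi


# ---------------------------------------------------------------------------
# de Bruijn-style counterbalancing sequences
# ---------------------------------------------------------------------------


def _hierholzer(adjacency: dict, start, n_edges: int) -> list:
    """Eulerian circuit on a directed graph given mutable adjacency lists.

    Standard Hierholzer stack algorithm; adjacency lists are consumed. The
    caller shuffles adjacency lists beforehand to randomize the circuit.
    """
    stack = [start]
    circuit = []
    while stack:
        v = stack[-1]
        if adjacency[v]:
            stack.append(adjacency[v].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    if len(circuit) != n_edges + 1:
        raise RuntimeError("graph is not Eulerian-connected")  # pragma: no cover
    return circuit


def generate_pair_debruijn(alphabet_size: int, rng=None) -> np.ndarray:
    """Cyclic sequence in which every ordered pair of distinct symbols
    occurs exactly once as a cyclic 2-window.

    This is an Eulerian circuit on the complete directed graph without
    self-loops, so the sequence has length ``k*(k-1)`` and never repeats a
    symbol immediately. ``rng`` randomizes the circuit.
    """
    k = int(alphabet_size)
    if k < 2:
        raise ValueError("alphabet_size must be >= 2")
    rng = np.random.default_rng(rng)
    adjacency = {}
    for a in range(k):
        nbrs = [b for b in range(k) if b != a]
        rng.shuffle(nbrs)
        adjacency[a] = nbrs
    circuit = _hierholzer(adjacency, int(rng.integers(k)), k * (k - 1))
    return np.asarray(circuit[:-1], dtype=int)  # drop the closing node: cyclic


def generate_triple_debruijn(alphabet_size: int, rng=None) -> np.ndarray:
    """Cyclic sequence in which every ordered triple of pairwise-distinct
    symbols occurs exactly once as a cyclic 3-window.

    Nodes are ordered distinct pairs (a, b); each all-distinct triple
    (a, b, c) is the edge (a, b) -> (b, c). Every node has in-degree =
    out-degree = k - 2 and the pair graph is connected for k >= 4, so an
    Eulerian circuit of length ``k*(k-1)*(k-2)`` exists; its edge sequence,
    read as first symbols, is the desired cyclic sequence.
    """
    k = int(alphabet_size)
    if k < 4:
        raise ValueError(
            "alphabet_size must be >= 4: the ordered-pair graph with "
            "all-distinct triple edges is disconnected for smaller alphabets"
        )
    rng = np.random.default_rng(rng)
    adjacency = {}
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            nbrs = [(b, c) for c in range(k) if c != a and c != b]
            rng.shuffle(nbrs)
            adjacency[(a, b)] = nbrs
    n_edges = k * (k - 1) * (k - 2)
    a = int(rng.integers(k))
    b = int((a + 1 + rng.integers(k - 1)) % k)
    circuit = _hierholzer(adjacency, (a, b), n_edges)
    return np.asarray([p[0] for p in circuit[:-1]], dtype=int)


def build_master_sequence(alphabet_size: int, rng=None) -> np.ndarray:
    """Concatenate two copies of the triple sequence and three copies of the
    pair sequence (length 2*504 + 3*72 = 1224 for nine symbols).

    Both constituents are cyclic with no immediate repeats; the pair sequence
    is rotated so the seam between the last triple copy and the first pair
    copy does not create an immediate repeat (rotation preserves the cyclic
    window census).
    """
    rng = np.random.default_rng(rng)
    triple = generate_triple_debruijn(alphabet_size, rng)
    pair = generate_pair_debruijn(alphabet_size, rng)
    if pair[0] == triple[-1]:
        shift = int(np.argmax(pair != triple[-1]))
        pair = np.roll(pair, -shift)
    return np.concatenate([triple, triple, pair, pair, pair])


# ---------------------------------------------------------------------------
# Block construction
# ---------------------------------------------------------------------------


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "block": pd.Series(dtype=int),
            "onset_s": pd.Series(dtype=float),
            "orientation_deg": pd.Series(dtype=float),
            "sequence_type": pd.Series(dtype=object),
            "train_position": pd.Series(dtype=int),
            "train_length": pd.Series(dtype=int),
            "is_target": pd.Series(dtype=bool),
        }
    )


def build_roving_blocks(
    config: SequenceConfig,
    master: np.ndarray,
    start_offset: int = 0,
    rng=None,
    n_blocks: int | None = None,
) -> pd.DataFrame:
    """Roving-standard blocks: trains of a repeated orientation, whose
    orientations follow successive master-sequence symbols.

    Train lengths are drawn from the normalized weight distribution over the
    configured support; each block holds exactly ``gratings_per_block``
    events, the final train being truncated at the block boundary.
    """
    master = np.asarray(master)
    if master.size == 0:
        raise ValueError("master sequence is empty")
    rng = np.random.default_rng(rng)
    n_blocks = config.n_roving_blocks if n_blocks is None else n_blocks
    support = np.asarray(config.train_length_support)
    p = np.asarray(config.train_length_weights, dtype=float)
    p = p / p.sum()
    orientations = config.orientations

    rows = []
    pos = start_offset
    for block in range(n_blocks):
        n_emitted = 0
        while n_emitted < config.gratings_per_block:
            symbol = int(master[pos % master.size])
            pos += 1
            length = int(rng.choice(support, p=p))
            length = min(length, config.gratings_per_block - n_emitted)
            for j in range(length):
                rows.append(
                    (
                        block,
                        n_emitted * config.soa,
                        orientations[symbol],
                        "roving",
                        j + 1,
                        length,
                        False,
                    )
                )
                n_emitted += 1
    return pd.DataFrame(rows, columns=list(_empty_events().columns))


def build_equiprobable_blocks(
    config: SequenceConfig,
    master: np.ndarray,
    start_offset: int = 0,
    rng=None,
    n_blocks: int | None = None,
) -> pd.DataFrame:
    """Equiprobable control blocks: orientation changes on every presentation,
    following consecutive master-sequence symbols."""
    master = np.asarray(master)
    if master.size == 0:
        raise ValueError("master sequence is empty")
    n_blocks = config.n_equiprobable_blocks if n_blocks is None else n_blocks
    orientations = config.orientations
    rows = []
    pos = start_offset
    for block in range(n_blocks):
        for j in range(config.gratings_per_block):
            symbol = int(master[pos % master.size])
            pos += 1
            rows.append(
                (block, j * config.soa, orientations[symbol], "equiprobable", 1, 1, False)
            )
    return pd.DataFrame(rows, columns=list(_empty_events().columns))


def place_targets(
    events: pd.DataFrame,
    config: SequenceConfig,
    rng=None,
    max_retries: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mark target gratings and draw fixation-dot event onsets per block.

    Per block: exactly ``targets_per_block`` gratings are flagged as targets,
    balanced across orientations (2 per orientation in the default design),
    with every pair of target onsets at least ``min_target_gap`` apart. Dot
    events are onset times (not gratings) obeying the same minimum gap.

    Returns the events with ``is_target`` set, and a dot-event table
    (block, onset_s).
    """
    rng = np.random.default_rng(rng)
    events = events.copy()
    events["is_target"] = False
    per_orient = config.targets_per_block // config.n_orientations
    dot_rows = []
    for block, idx in events.groupby("block").groups.items():
        sub = events.loc[idx]
        if len(sub) < config.targets_per_block:
            raise ValueError(f"block {block} has too few events for targets")
        chosen = _place_block_targets(sub, config, per_orient, rng, max_retries)
        events.loc[chosen, "is_target"] = True
        block_dur = len(sub) * config.soa
        for onset in _draw_gapped_onsets(
            config.dot_events_per_block, block_dur, config.min_target_gap, rng, max_retries
        ):
            dot_rows.append((block, onset))
    dots = pd.DataFrame(dot_rows, columns=["block", "onset_s"])
    return events, dots


def _place_block_targets(sub, config, per_orient, rng, max_retries):
    onset_of = dict(zip(sub.index, sub["onset_s"]))
    orients = sub["orientation_deg"].to_numpy()
    index = sub.index.to_numpy()
    for _ in range(max_retries):
        chosen: list = []
        chosen_onsets: list = []
        ok = True
        for orient in rng.permutation(config.orientations):
            cand = index[orients == orient]
            rng.shuffle(cand)
            got = 0
            for c in cand:
                t = onset_of[c]
                if all(abs(t - u) >= config.min_target_gap for u in chosen_onsets):
                    chosen.append(c)
                    chosen_onsets.append(t)
                    got += 1
                    if got == per_orient:
                        break
            if got < per_orient:
                ok = False
                break
        if ok:
            return chosen
    raise RuntimeError("target placement failed after bounded retries")


def _draw_gapped_onsets(n, duration, min_gap, rng, max_retries=None):
    """Uniform draw of n onsets in [0, duration] with pairwise gaps >= min_gap,
    via the spacing construction (shrink, sample, re-inflate)."""
    slack = duration - (n - 1) * min_gap
    if slack <= 0:
        raise RuntimeError("dot-event placement infeasible: gaps exceed block duration")
    return np.sort(rng.uniform(0, slack, size=n)) + min_gap * np.arange(n)


# ---------------------------------------------------------------------------
# Condition labelling and mismatch coding
# ---------------------------------------------------------------------------


def wrap_mismatch(delta) -> np.ndarray:
    """Map an orientation difference (deg) into the signed half-open interval
    (-90, 90] of the 180-degree circular space."""
    d = np.mod(np.asarray(delta, dtype=float), 180.0)
    return np.where(d > 90.0, d - 180.0, d)


def label_conditions(
    events: pd.DataFrame,
    attention: str,
    standard_window: tuple | None = None,
) -> pd.DataFrame:
    """Assign condition labels, mismatch angles, and attention.

    deviant: first event of a train in a roving block; standard: repetition
    count inside ``standard_window`` (default 5..7); control: every
    equiprobable event; everything else unlabelled. ``mismatch_deg`` is the
    signed circular difference (current - previous orientation) in (-90, 90];
    it is NaN for the first event of each block. ``n_preceding_standards`` is
    the previous train's length, recorded for deviants.
    """
    if attention not in ("attended", "ignored"):
        raise ValueError("attention must be 'attended' or 'ignored'")
    if standard_window is None:
        standard_window = (5, 7)
    lo, hi = standard_window
    out = events.copy()
    out["attention"] = attention

    cond = np.full(len(out), "unlabelled", dtype=object)
    roving = out["sequence_type"].to_numpy() == "roving"
    tp = out["train_position"].to_numpy()
    cond[roving & (tp == 1)] = "deviant"
    cond[roving & (tp >= lo) & (tp <= hi)] = "standard"
    cond[~roving] = "control"
    out["condition"] = cond

    orient = out["orientation_deg"].to_numpy()
    mismatch = np.full(len(out), np.nan)
    blocks = out["block"].to_numpy()
    seqtype = out["sequence_type"].to_numpy()
    # a previous stimulus exists only within the same block and sequence type
    prev_in_block = np.empty(len(out), dtype=bool)
    prev_in_block[0] = False
    prev_in_block[1:] = (blocks[1:] == blocks[:-1]) & (seqtype[1:] == seqtype[:-1])
    mismatch[1:] = wrap_mismatch(orient[1:] - orient[:-1])
    mismatch[~prev_in_block] = np.nan
    out["mismatch_deg"] = mismatch

    n_prec = np.full(len(out), 0, dtype=int)
    tlen = out["train_length"].to_numpy()
    is_dev = cond == "deviant"
    for i in np.flatnonzero(is_dev):
        if prev_in_block[i]:
            n_prec[i] = tlen[i - 1]
    out["n_preceding_standards"] = n_prec
    return out[EVENT_COLUMNS]


def simulate_design(config: SequenceConfig, attention: str, seed=None) -> pd.DataFrame:
    """End-to-end design generation for one session: master sequence, roving +
    equiprobable blocks, targets, condition labels.

    Equiprobable blocks are appended after the roving blocks with continuing
    block indices. Returns the labelled event table (dot events are placed but
    only the grating table is returned; use :func:`place_targets` directly if
    dot onsets are needed).
    """
    rng = np.random.default_rng(seed)
    master = build_master_sequence(config.n_orientations, rng)
    start = int(rng.integers(master.size))
    roving = build_roving_blocks(config, master, start, rng)
    equi = build_equiprobable_blocks(config, master, int(rng.integers(master.size)), rng)
    equi = equi.assign(block=equi["block"] + config.n_roving_blocks)
    events = pd.concat([roving, equi], ignore_index=True)
    events, _ = place_targets(events, config, rng)
    return label_conditions(events, attention, config.standard_window)
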