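"""Structured-coalescent simulation under an isolation (no-migration) history.

A :class:`DemographicModel` is a set of demes with haploid effective sizes
and sample sizes, plus a time-ordered list of merge events that (going
backwards in time) move the surviving lineages of one or more source demes
into a destination deme with its own size.  Within a deme of haploid size N
holding k lineages, coalescence waiting times are exponential with rate
k(k-1)/(2N) per generation (continuous-time Kingman approximation, standard
for N much larger than k).

Sequence evolution is an event-based finite-sites process: the root
sequence is drawn from the base frequencies, each branch receives a
Poisson(mu * L * branch length) number of substitutions, and each
substitution hits a uniform site, producing a transition with probability
``ts_proportion`` and otherwise one of the two transversions equiprobably.
Multiple hits are therefore possible, as in real mtDNA.

Times are in generations; mutation rates in substitutions/site/year, linked
by the model's generation time (1 year for these toads).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .seq_io import Alignment

__all__ = [
    "Deme",
    "MergeEvent",
    "DemographicModel",
    "MutationModel",
    "Genealogy",
    "simulate_genealogy",
    "evolve_sequences",
    "load_scenario",
    "rhinella_mtdna_model",
]


@dataclass(frozen=True)
class Deme:
    name: str
    size: float  # haploid effective size (gene copies)
    nsamples: int = 0


@dataclass(frozen=True)
class MergeEvent:
    """At ``time`` generations ago, lineages in ``sources`` move to ``dest``."""

    time: float
    sources: tuple[str, ...]
    dest: str
    dest_size: float


@dataclass(frozen=True)
class DemographicModel:
    demes: tuple[Deme, ...]
    events: tuple[MergeEvent, ...]
    generation_time: float = 1.0  # years per generation

    def validate(self) -> None:
        names = [d.name for d in self.demes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate deme names")
        for d in self.demes:
            if d.size <= 0:
                raise ValueError(f"deme {d.name}: size must be > 0")
            if d.nsamples < 0:
                raise ValueError(f"deme {d.name}: negative sample size")
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        # every sampled lineage must reach a single root deme
        alive = set(names)
        for e in self.events:
            if e.dest_size <= 0:
                raise ValueError("event destination size must be > 0")
            unknown = set(e.sources) - alive
            if unknown:
                raise ValueError(f"event at {e.time}: unknown sources {unknown}")
            alive -= set(e.sources)
            alive.add(e.dest)
        if len(alive) != 1:
            raise ValueError(
                f"history must end in a single root deme, got {sorted(alive)}"
            )

    @property
    def total_samples(self) -> int:
        return sum(d.nsamples for d in self.demes)


@dataclass(frozen=True)
class MutationModel:
    """Finite-sites substitution process with transition bias."""

    mu: float  # substitutions per site per year
    L: int  # sites
    ts_proportion: float = 0.9
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.mu < 0 or self.L < 1:
            raise ValueError("need mu >= 0 and L >= 1")
        if not (0.0 < self.ts_proportion < 1.0):
            raise ValueError("ts_proportion must be in (0,1)")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")


@dataclass(frozen=True)
class Genealogy:
    """Rooted binary coalescent tree, ultrametric in generations.

    Nodes 0..n_tips-1 are tips (time 0); internal nodes follow in
    coalescence order; the last node is the root.  ``parent[i]`` is -1 for
    the root.  ``tip_labels``/``tip_demes`` record sample identity.
    """

    n_tips: int
    parent: np.ndarray  # (2n-1,) int
    time: np.ndarray  # (2n-1,) float, generations before present
    tip_labels: tuple[str, ...]
    tip_demes: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1 if self.n_tips > 1 else 1

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    def branch_lengths(self) -> np.ndarray:
        """Per-node branch length to its parent (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 1):
            bl[i] = self.time[self.parent[i]] - self.time[i]
        return bl

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())


def simulate_genealogy(
    model: DemographicModel, seed: int | np.random.Generator | None = None
) -> Genealogy:
    """Simulate one gene genealogy under the isolation history.

    Returns the full coalescent tree of all sampled lineages; with a single
    sampled lineage the genealogy has one node and no branches.
    """
    model.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = model.total_samples
    if n < 1:
        raise ValueError("no samples in model")

    tip_labels, tip_demes = [], []
    lineages: dict[str, list[int]] = {}
    node = 0
    for d in model.demes:
        lineages[d.name] = []
        for i in range(d.nsamples):
            tip_labels.append(f"{d.name}_{i:03d}")
            tip_demes.append(d.name)
            lineages[d.name].append(node)
            node += 1
    if n == 1:
        return Genealogy(1, np.array([-1]), np.zeros(1),
                         tuple(tip_labels), tuple(tip_demes))

    sizes = {d.name: float(d.size) for d in model.demes}
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    next_node = n
    t = 0.0
    events = list(model.events) + [None]  # sentinel: no further events

    for ev in events:
        horizon = ev.time if ev is not None else np.inf
        while True:
            # total coalescence rate over active demes
            waits = {}
            for name, lins in lineages.items():
                k = len(lins)
                if k >= 2:
                    rate = k * (k - 1) / (2.0 * sizes[name])
                    waits[name] = rng.exponential(1.0 / rate)
            if not waits:
                break
            deme = min(waits, key=waits.get)
            dt = waits[deme]
            if t + dt >= horizon:
                break
            t += dt
            lins = lineages[deme]
            i = int(rng.integers(len(lins)))
            j = int(rng.integers(len(lins) - 1))
            if j >= i:
                j += 1
            a, b = lins[i], lins[j]
            parent[a] = parent[b] = next_node
            time[next_node] = t
            for idx in sorted((i, j), reverse=True):
                lins.pop(idx)
            lins.append(next_node)
            next_node += 1
            if next_node == n_nodes:
                break
        if ev is None:
            break
        t = ev.time
        moved = []
        for src in ev.sources:
            moved.extend(lineages.pop(src, []))
        lineages.setdefault(ev.dest, []).extend(moved)
        sizes[ev.dest] = float(ev.dest_size)

    if next_node != n_nodes:
        # should be unreachable for a valid model (validated above)
        raise RuntimeError("simulation ended before full coalescence")
    return Genealogy(n, parent, time, tuple(tip_labels), tuple(tip_demes))


_TRANSITION = np.array([1, 0, 3, 2], dtype=np.int8)  # A<->G, C<->T
_TRANSVERSIONS = np.array(
    [[2, 3], [2, 3], [0, 1], [0, 1]], dtype=np.int8
)  # for A,G: C/T; for C,T: A/G


def evolve_sequences(
    g: Genealogy,
    mm: MutationModel,
    generation_time: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> Alignment:
    """Evolve sequences down the genealogy; returns the tip alignment.

    The per-generation rate is mu * generation_time (mu is per year).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate_per_gen = mm.mu * generation_time
    root = g.n_nodes - 1
    seqs = [None] * g.n_nodes
    seqs[root] = rng.choice(4, size=mm.L, p=np.asarray(mm.base_freqs)).astype(np.int8)

    if g.n_tips == 1:
        return Alignment.from_codes(g.tip_labels, seqs[root][None, :])

    children: list[list[int]] = [[] for _ in range(g.n_nodes)]
    for i in range(g.n_nodes - 1):
        children[g.parent[i]].append(i)

    bl = g.branch_lengths()
    stack = [root]
    while stack:
        u = stack.pop()
        for v in children[u]:
            seq = seqs[u].copy()
            nmut = rng.poisson(rate_per_gen * mm.L * bl[v])
            for _ in range(nmut):
                site = int(rng.integers(mm.L))
                cur = seq[site]
                if rng.random() < mm.ts_proportion:
                    seq[site] = _TRANSITION[cur]
                else:
                    seq[site] = _TRANSVERSIONS[cur, int(rng.integers(2))]
            seqs[v] = seq
            stack.append(v)
    tips = np.stack([seqs[i] for i in range(g.n_tips)])
    return Alignment.from_codes(g.tip_labels, tips)


# ---------------------------------------------------------------------------
# scenario files
# ---------------------------------------------------------------------------

def _model_from_dict(doc: dict) -> tuple[DemographicModel, MutationModel, dict]:
    demes = tuple(
        Deme(d["name"], float(d["size"]), int(d.get("samples", 0)))
        for d in doc["demes"]
    )
    events = tuple(
        MergeEvent(
            float(e["time"]), tuple(e["sources"]), e["dest"], float(e["dest_size"])
        )
        for e in doc.get("events", [])
    )
    model = DemographicModel(
        demes, events, generation_time=float(doc.get("generation_time", 1.0))
    )
    model.validate()
    mut = doc.get("mutation", {})
    mm = MutationModel(
        mu=float(mut["mu"]),
        L=int(mut["L"]),
        ts_proportion=float(mut.get("ts_proportion", 0.9)),
        base_freqs=tuple(mut.get("base_freqs", (0.25, 0.25, 0.25, 0.25))),
    )
    meta = {k: doc[k] for k in ("name", "focal") if k in doc}
    return model, mm, meta


def load_scenario(name_or_path: str | Path) -> tuple[DemographicModel, MutationModel, dict]:
    """Load a demographic scenario from YAML.

    ``name_or_path`` is either a filesystem path or the name of a packaged
    scenario (currently ``rhinella_mtdna``).  Returns (model, mutation
    model, metadata) where metadata carries the scenario name and the
    default focal group.
    """
    p = Path(name_or_path)
    if p.exists():
        text = p.read_text()
    else:
        ref = importlib.resources.files("cytodiscord.scenarios").joinpath(
            f"{name_or_path}.yaml"
        )
        if not ref.is_file():
            raise FileNotFoundError(f"no such scenario file or name: {name_or_path}")
        text = ref.read_text()
    return _model_from_dict(yaml.safe_load(text))


def rhinella_mtdna_model() -> tuple[DemographicModel, MutationModel, dict]:
    """The packaged mtDNA scenario of the toad study (nuclear-inferred history).

    Three demes (LAB/RAB *R. marina*, SCH *R. schneideri*) with haploid
    sizes 69k/190k/143k and mtDNA sample sizes 22/43/27; LAB+RAB merge into
    a 63k ancestor 325k generations ago; the final merge with SCH into a
    103k root is 1.69M generations ago; mu = 0.69e-8/site/year over 327 bp.
    """
    return load_scenario("rhinella_mtdna")
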