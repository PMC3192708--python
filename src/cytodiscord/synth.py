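"""Synthetic study generator: four loci emulating the toad dataset.

Generates per-locus alignments with the sample structure of the empirical
study — one mtDNA locus (cyt b, 327 bp; LAB 22 / RAB 43 / SCH 27) and
three nuclear intron loci (RPL9 495, RPL3 665, c-myc 578 net sites with
their own sample sizes) — under one of two histories:

``concordant``
    every locus evolves on the species history ((LAB,RAB),SCH): splits at
    325k and 1.69M generations ago.
``mtdna_capture``
    nuclear loci evolve on the species history, but the mtDNA genealogy
    follows an introgression history in which the RAB mitochondrial
    lineage derives from *R. schneideri*: RAB and SCH mtDNA share a recent
    ancestral deme (the capture time, default 100k generations — a
    modeling choice, not an empirical estimate) while LAB diverges at the
    deep split.  This reproduces the study's cytonuclear-discordance
    signature: nuclear fixed differences between the species with
    essentially none between RAB and SCH mtDNA.

Nuclear deme sizes are the mtDNA haploid sizes scaled by 4 (diploid
autosomal loci have four times the effective copy number of a haploid
uniparental locus).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalsim import (
    Deme,
    DemographicModel,
    MergeEvent,
    MutationModel,
    evolve_sequences,
    simulate_genealogy,
)
from .seq_io import Alignment, GroupMap, write_alignment, write_group_map

__all__ = ["LocusSpec", "StudyScenario", "StudyData", "generate_study", "write_study"]

#: mtDNA-scale haploid effective sizes (gene copies) of the study history.
_MT_SIZES = {"LAB": 69_000, "RAB": 190_000, "SCH": 143_000,
             "ANC1": 63_000, "ROOT": 103_000}
_SPLIT_SHALLOW = 325_000  # LAB/RAB, generations
_SPLIT_DEEP = 1_690_000  # marina/schneideri, generations
_NUCLEAR_SCALE = 4


@dataclass(frozen=True)
class LocusSpec:
    name: str
    L: int
    mu: float  # substitutions/site/year
    ts_proportion: float
    samples: dict  # group label -> sample size
    nuclear: bool


#: the four study loci: lengths are the net site counts of the empirical
#: alignments; nuclear mu is the Neotropical c-myc calibration, mtDNA mu
#: the bufonid cyt b rate.
STUDY_LOCI: tuple[LocusSpec, ...] = (
    LocusSpec("cytb", 327, 0.69e-8, 0.9,
              {"LAB": 22, "RAB": 43, "SCH": 27}, nuclear=False),
    LocusSpec("RPL9", 495, 2.01e-9, 0.5,
              {"LAB": 20, "RAB": 44, "SCH": 30}, nuclear=True),
    LocusSpec("RPL3", 665, 2.01e-9, 0.5,
              {"LAB": 16, "RAB": 64, "SCH": 30}, nuclear=True),
    LocusSpec("cmyc", 578, 2.01e-9, 0.5,
              {"LAB": 10, "RAB": 42, "SCH": 24}, nuclear=True),
)


@dataclass(frozen=True)
class StudyScenario:
    """Mode, capture time and master seed fully determine the dataset."""

    mode: str = "mtdna_capture"
    seed: int | None = None
    capture_time: float = 100_000
    loci: tuple[LocusSpec, ...] = STUDY_LOCI

    def __post_init__(self) -> None:
        if self.mode not in {"concordant", "mtdna_capture"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.capture_time < _SPLIT_DEEP):
            raise ValueError("capture_time must lie inside (0, deep split)")


@dataclass(frozen=True)
class StudyData:
    scenario: StudyScenario
    alignments: dict  # locus name -> Alignment
    group_map: GroupMap


def _species_history(samples: dict, scale: int) -> DemographicModel:
    s = {k: v * scale for k, v in _MT_SIZES.items()}
    demes = tuple(
        Deme(g, s[g], samples.get(g, 0)) for g in ("LAB", "RAB", "SCH")
    )
    events = (
        MergeEvent(_SPLIT_SHALLOW, ("LAB", "RAB"), "ANC1", s["ANC1"]),
        MergeEvent(_SPLIT_DEEP, ("ANC1", "SCH"), "ROOT", s["ROOT"]),
    )
    return DemographicModel(demes, events)


def _capture_history(samples: dict, capture_time: float) -> DemographicModel:
    # RAB mtDNA derives from SCH: shared recent ancestor at the capture
    # time (size = SCH's, the donor lineage), LAB splits at the deep time.
    s = _MT_SIZES
    demes = tuple(
        Deme(g, s[g], samples.get(g, 0)) for g in ("LAB", "RAB", "SCH")
    )
    events = (
        MergeEvent(capture_time, ("RAB", "SCH"), "ANC_RS", s["SCH"]),
        MergeEvent(_SPLIT_DEEP, ("LAB", "ANC_RS"), "ROOT", s["ROOT"]),
    )
    return DemographicModel(demes, events)


def demographic_model_for(locus: LocusSpec, scenario: StudyScenario) -> DemographicModel:
    """History a locus evolves on, given the scenario mode."""
    if locus.nuclear:
        return _species_history(locus.samples, _NUCLEAR_SCALE)
    if scenario.mode == "concordant":
        return _species_history(locus.samples, 1)
    return _capture_history(locus.samples, scenario.capture_time)


def generate_study(scenario: StudyScenario) -> StudyData:
    """Simulate all loci; byte-identical output for equal master seeds."""
    ss = np.random.SeedSequence(scenario.seed)
    alignments: dict[str, Alignment] = {}
    mapping: dict[str, str] = {}
    for locus, child in zip(scenario.loci, ss.spawn(len(scenario.loci))):
        model = demographic_model_for(locus, scenario)
        mm = MutationModel(mu=locus.mu, L=locus.L, ts_proportion=locus.ts_proportion)
        rng = np.random.default_rng(child)
        g = simulate_genealogy(model, rng)
        aln = evolve_sequences(g, mm, model.generation_time, rng)
        alignments[locus.name] = aln
        for lab, deme in zip(g.tip_labels, g.tip_demes):
            mapping.setdefault(lab, deme)
    return StudyData(scenario, alignments, GroupMap(mapping))


def discordance_signature(data: StudyData) -> dict:
    """Score the study's cytonuclear-discordance pattern on one dataset.

    Reconstructs an NJ/K2P tree per locus and asks whether (i) the pooled
    *R. marina* sample (LAB+RAB) is NOT monophyletic at the mtDNA locus —
    SCH haplotypes fall inside the marina radiation — while (ii) the
    nuclear loci support marina monophyly (majority rule over the three
    loci, acknowledging residual nuclear lineage sorting).  Returns a dict
    with per-locus monophyly calls and the overall boolean under
    ``"discordant"``.
    """
    from .trees import k2p_distance, monophyly_edge_length, neighbor_joining

    marina_groups = {"LAB", "RAB"}
    calls: dict[str, bool] = {}
    for locus in data.scenario.loci:
        aln = data.alignments[locus.name]
        marina = [
            sid for sid in aln.ids if data.group_map[sid] in marina_groups
        ]
        tree = neighbor_joining(k2p_distance(aln), aln.ids)
        length = monophyly_edge_length(tree, marina)
        calls[locus.name] = length is not None and length > 0.0
    nuclear = [l.name for l in data.scenario.loci if l.nuclear]
    mtdna = [l.name for l in data.scenario.loci if not l.nuclear]
    nuclear_support = sum(calls[n] for n in nuclear) >= (len(nuclear) // 2 + 1)
    mt_discordant = not calls[mtdna[0]]
    return {
        "marina_monophyly": calls,
        "nuclear_support": nuclear_support,
        "mtdna_marina_non_monophyletic": mt_discordant,
        "discordant": nuclear_support and mt_discordant,
    }


def write_study(data: StudyData, outdir: str | Path) -> list[Path]:
    """Write one FASTA per locus, a groups TSV and a scenario JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, aln in data.alignments.items():
        p = outdir / f"{name}.fasta"
        write_alignment(aln, p)
        written.append(p)
    p = outdir / "groups.tsv"
    write_group_map(data.group_map, p)
    written.append(p)
    sc = data.scenario
    doc = {
        "mode": sc.mode,
        "seed": sc.seed,
        "capture_time": sc.capture_time,
        "loci": [
            {"name": l.name, "L": l.L, "mu": l.mu,
             "ts_proportion": l.ts_proportion, "samples": l.samples,
             "nuclear": l.nuclear}
            for l in sc.loci
        ],
    }
    p = outdir / "scenario.json"
    p.write_text(json.dumps(doc, indent=2) + "\n")
    written.append(p)
    return written
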