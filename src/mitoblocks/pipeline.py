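"""Orchestration of the full pairwise comparison.

repeats → anchors → blocks → signed permutation → junction associations →
repeat-mediated inversion scenarios, gathered in one machine-readable
report.  Repeats and scenario placements are computed on genome B, the
putatively rearranged genome; the scenario search runs backward from the
observed block order to the identity (placements are only observable in
the extant genome) and the event lists are reversed for reporting, which
is exact because inversions are involutions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .genome import AnnotatedGenome
from .lcb import (
    JunctionAssociation,
    blocks_table,
    blocks_to_permutation,
    chain_anchors,
    find_anchors,
    junction_repeat_association,
    junctions_table,
)
from .rearrange import (
    RepeatPlacement,
    Scenario,
    find_repeat_mediated_scenarios,
    identity_permutation,
)
from .repeats import find_repeat_pairs, repeats_table


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Every threshold of the analysis, reachable from YAML and the CLI."""

    repeat_min_len: int = 100
    repeat_min_identity: float = 0.90
    repeat_seed_k: int = 21
    min_anchor_len: int = 25
    max_gap: int = 5000
    min_block: int = 1000
    junction_window: int = 100
    max_events: int = 4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


@dataclass
class ComparisonReport:
    schema: int
    genomeA: str
    genomeB: str
    blocks: list
    permutation: tuple[int, ...]
    repeats: list
    junctions: list
    placements: list
    scenarios: list[Scenario]
    rearranged: bool
    config: PipelineConfig = field(repr=False, default=None)

    def to_json(self, path=None) -> str:
        doc = {
            "schema": self.schema,
            "genomeA": self.genomeA,
            "genomeB": self.genomeB,
            "rearranged": self.rearranged,
            "permutation": list(self.permutation),
            "blocks": [
                {
                    "label": b.label,
                    "A_start": b.intervalA.start, "A_end": b.intervalA.end,
                    "B_start": b.intervalB.start, "B_end": b.intervalB.end,
                    "sign": b.sign, "n_anchors": b.n_anchors,
                }
                for b in self.blocks
            ],
            "repeats": [
                {
                    "label": p.label,
                    "copy1": [p.copy1.start, p.copy1.end],
                    "copy2": [p.copy2.start, p.copy2.end],
                    "orientation": p.orientation,
                    "length": p.length,
                    "identity_pct": round(p.identity_pct, 1),
                }
                for p in self.repeats
            ],
            "junctions": [
                {
                    "junction": a.junction,
                    "repeat": a.repeat_label,
                    "distance_bp": a.distance,
                    "intergenic": a.intergenic,
                }
                for a in self.junctions
            ],
            "placements": [asdict(pl) for pl in self.placements],
            "scenarios": [
                {
                    "events": [
                        {"segment": list(ev.segment),
                         "mediating_repeat": ev.mediating_repeat}
                        for ev in sc.events
                    ],
                    "intermediate_orders": [list(p) for p in sc.intermediates()],
                }
                for sc in self.scenarios
            ],
            "config": asdict(self.config) if self.config else None,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _placements_from_junctions(
    blocks, junctions: list[JunctionAssociation], repeats
) -> list[RepeatPlacement]:
    """Block-scale repeat placements: a pair whose two copies sit at two
    distinct junctions of the observed block order."""
    order = sorted(blocks, key=lambda b: b.intervalB.start)
    jindex = {
        f"{x.label}-{y.label}": i + 1 for i, (x, y) in enumerate(zip(order, order[1:]))
    }
    by_label: dict[str, set[int]] = {}
    for a in junctions:
        if a.repeat_label is not None:
            by_label.setdefault(a.repeat_label, set()).add(jindex[a.junction])
    placements = []
    for rp in repeats:
        label = rp.label
        if label is None:
            continue
        js = sorted(by_label.get(label, ()))
        if len(js) == 2:
            placements.append(
                RepeatPlacement(label, js[0], js[1], rp.orientation)
            )
    return placements


def compare_genomes(
    genomeA: AnnotatedGenome,
    genomeB: AnnotatedGenome,
    config: PipelineConfig | None = None,
) -> ComparisonReport:
    """Full comparison of a reference (A) against an observed genome (B)."""
    cfg = config or PipelineConfig()

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise PipelineError(f"stage {name}: {exc}") from exc

    repeats = stage(
        "find_repeat_pairs", find_repeat_pairs, genomeB,
        min_len=cfg.repeat_min_len, min_identity=cfg.repeat_min_identity,
        k=cfg.repeat_seed_k,
    )
    # give anonymous pairs stable labels (length rank order)
    from dataclasses import replace as _dc_replace

    repeats = [
        p if p.label else _dc_replace(p, label=f"P{i}")
        for i, p in enumerate(repeats, 1)
    ]

    anchors = stage(
        "find_anchors", find_anchors, genomeA, genomeB,
        min_anchor_len=cfg.min_anchor_len,
    )
    blocks = stage(
        "chain_anchors", chain_anchors, anchors,
        max_gap=cfg.max_gap, min_block=cfg.min_block,
    )
    perm = stage("blocks_to_permutation", blocks_to_permutation, blocks)
    junctions = stage(
        "junction_repeat_association", junction_repeat_association,
        blocks, repeats, genomeB, window=cfg.junction_window,
    )
    placements = stage(
        "placements", _placements_from_junctions, blocks, junctions, repeats
    )
    identity = identity_permutation(len(perm))
    rearranged = perm != identity
    scenarios: list[Scenario] = []
    if rearranged and perm:
        backward = stage(
            "find_repeat_mediated_scenarios", find_repeat_mediated_scenarios,
            perm, identity, placements, max_events=cfg.max_events,
        )
        scenarios = [sc.reversed_() for sc in backward]
    return ComparisonReport(
        schema=1,
        genomeA=genomeA.id,
        genomeB=genomeB.id,
        blocks=blocks,
        permutation=perm,
        repeats=repeats,
        junctions=junctions,
        placements=placements,
        scenarios=scenarios,
        rearranged=rearranged,
        config=cfg,
    )


def report_tables(report: ComparisonReport) -> dict:
    """Per-module TSV sidecar tables of a comparison report."""
    return {
        "blocks": blocks_table(report.blocks),
        "repeats": repeats_table(report.repeats),
        "junctions": junctions_table(report.junctions),
    }
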