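"""Multiplex qPCR panel description.

A *panel* is the assay design for relative-quantification copy-number
typing: a set of marker assays (each a primer/probe combination on one
fluorophore channel), grouped into multiplex reactions that co-amplify one
or two targets together with an endogenous reference gene of fixed copy
number (two copies per diploid genome).  The bundled KIR panel follows the
published qKAT design: 20 target markers over the KIR genes and their
important variants, typed in ten triplex reactions against STAT6, in
quadruplicate on 384-well plates with three known-copy-number controls per
run.

The exact pairing of the 20 KIR markers into the ten reactions is not part
of the public assay description; the bundled pairing is arbitrary but fixed
and documented in the panel file itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLUMNS = 24
PLATE_WELLS = len(PLATE_ROWS) * PLATE_COLUMNS  # 384

#: name of the bundled full KIR panel, loadable via :func:`builtin_panel`.
KIR_PANEL = "kir"


class PanelError(ValueError):
    """Raised when a panel file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class MarkerAssay:
    """One primer/probe assay: a marker on a single fluorophore channel."""

    marker_id: str
    gene: str
    region_label: str = ""
    channel: str = ""
    is_reference: bool = False


@dataclass(frozen=True)
class MultiplexReaction:
    """A multiplex well recipe: 1 (duplex) or 2 (triplex) targets + reference."""

    reaction_id: str
    target_markers: tuple[str, ...]
    reference_marker: str

    @property
    def all_markers(self) -> tuple[str, ...]:
        return self.target_markers + (self.reference_marker,)


@dataclass
class Panel:
    """A validated multiplex copy-number assay design.

    ``paired_assays`` lists marker pairs that interrogate the same gene in
    two places (used for allele-dropout detection); ``sum_rules`` lists
    (total marker, component markers) consistency constraints, e.g. the
    2DS4 assay total must equal the full-length plus deletion variants.
    """

    name: str
    markers: list[MarkerAssay]
    reactions: list[MultiplexReaction]
    reference_copy_number: int = 2
    replicates: int = 4
    paired_assays: list[tuple[str, str]] = field(default_factory=list)
    sum_rules: list[tuple[str, list[str]]] = field(default_factory=list)

    # Construction is unchecked so that validate_panel can report on broken
    # panels; the file loaders reject any panel with violations.

    # -- lookups -----------------------------------------------------------
    def marker(self, marker_id: str) -> MarkerAssay:
        try:
            return self._marker_index[marker_id]
        except AttributeError:
            object.__setattr__(self, "_marker_index", {m.marker_id: m for m in self.markers})
            return self._marker_index[marker_id]

    def reaction(self, reaction_id: str) -> MultiplexReaction:
        for r in self.reactions:
            if r.reaction_id == reaction_id:
                return r
        raise KeyError(reaction_id)

    @property
    def target_markers(self) -> list[MarkerAssay]:
        return [m for m in self.markers if not m.is_reference]

    @property
    def reference_markers(self) -> list[MarkerAssay]:
        return [m for m in self.markers if m.is_reference]

    @property
    def n_primer_pairs(self) -> int:
        """One primer pair per marker assay, reference included."""
        return len(self.markers)

    @property
    def sum_rule_totals(self) -> set[str]:
        return {total for total, _ in self.sum_rules}


@dataclass
class PlateLayout:
    """Assignment of (sample, reaction, replicate) triples to 384 wells."""

    plate_id: str
    wells: dict[str, tuple[str, str, int]]
    control_samples: list[tuple[str, dict[str, int]]] = field(default_factory=list)

    def wells_for_sample(self, sample_id: str) -> list[str]:
        return [w for w, (s, _, _) in self.wells.items() if s == sample_id]


# ---------------------------------------------------------------------------
# validation


def validate_panel(panel: Panel) -> list[str]:
    """Return a list of violations; empty for a valid panel."""
    problems: list[str] = []
    ids = [m.marker_id for m in panel.markers]
    known = set(ids)
    if len(known) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        problems.append(f"duplicate marker ids: {dupes}")
    if not any(m.is_reference for m in panel.markers):
        problems.append("no reference marker declared")
    if panel.reference_copy_number < 1:
        problems.append("reference_copy_number must be >= 1")
    if panel.replicates < 1:
        problems.append("replicates must be >= 1")

    seen_reactions = set()
    for r in panel.reactions:
        if r.reaction_id in seen_reactions:
            problems.append(f"duplicate reaction id {r.reaction_id!r}")
        seen_reactions.add(r.reaction_id)
        if not 1 <= len(r.target_markers) <= 2:
            problems.append(f"{r.reaction_id}: reactions carry 1 or 2 targets")
        for mid in r.all_markers:
            if mid not in known:
                problems.append(f"{r.reaction_id}: dangling reference to marker {mid!r}")
        present = [mid for mid in r.all_markers if mid in known]
        channels = [panel.marker(mid).channel for mid in present]
        if len(set(channels)) != len(channels):
            problems.append(f"{r.reaction_id}: channel clash ({channels})")
        if r.reference_marker in known and not panel.marker(r.reference_marker).is_reference:
            problems.append(f"{r.reaction_id}: reference marker {r.reference_marker!r} is not flagged is_reference")
        for mid in r.target_markers:
            if mid in known and panel.marker(mid).is_reference:
                problems.append(f"{r.reaction_id}: target {mid!r} is a reference assay")

    target_counts: dict[str, int] = {}
    for r in panel.reactions:
        for mid in r.target_markers:
            target_counts[mid] = target_counts.get(mid, 0) + 1
    for mid, n in target_counts.items():
        if n > 1:
            problems.append(f"marker {mid!r} targeted by {n} reactions")

    for a, b in panel.paired_assays:
        for mid in (a, b):
            if mid not in known:
                problems.append(f"paired_assays: dangling reference to marker {mid!r}")
    for total, components in panel.sum_rules:
        for mid in [total, *components]:
            if mid not in known:
                problems.append(f"sum_rules: dangling reference to marker {mid!r}")
    return problems


# ---------------------------------------------------------------------------
# loading


def _as_panel(doc: Mapping) -> Panel:
    try:
        markers = [
            MarkerAssay(
                marker_id=str(m["id"]),
                gene=str(m.get("gene", m["id"])),
                region_label=str(m.get("region", "")),
                channel=str(m.get("channel", "")),
                is_reference=bool(m.get("reference", False)),
            )
            for m in doc["markers"]
        ]
        reactions = [
            MultiplexReaction(
                reaction_id=str(r["id"]),
                target_markers=tuple(str(t) for t in r["targets"]),
                reference_marker=str(r["reference"]),
            )
            for r in doc["reactions"]
        ]
        paired = [tuple(p) for p in doc.get("paired_assays", [])]
        sums = [(str(s["total"]), [str(c) for c in s["components"]]) for s in doc.get("sum_rules", [])]
        panel = Panel(
            name=str(doc.get("name", "unnamed")),
            markers=markers,
            reactions=reactions,
            reference_copy_number=int(doc.get("reference_copy_number", 2)),
            replicates=int(doc.get("replicates", 4)),
            paired_assays=paired,  # type: ignore[arg-type]
            sum_rules=sums,
        )
    except (KeyError, TypeError) as exc:
        raise PanelError(f"malformed panel document: missing/invalid field {exc}") from exc
    problems = validate_panel(panel)
    if problems:
        raise PanelError(f"invalid panel {panel.name!r}: " + "; ".join(problems))
    return panel


def load_panel(path: str | Path) -> Panel:
    """Load and validate a panel from a YAML config file."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise PanelError(f"cannot parse panel file {path}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise PanelError(f"panel file {path} does not contain a mapping")
    return _as_panel(doc)


def builtin_panel(name: str = KIR_PANEL) -> Panel:
    """Load a bundled panel by name (currently only the full KIR panel)."""
    resource = resources.files("qkat.data").joinpath(f"{name}_panel.yaml")
    if not resource.is_file():
        raise PanelError(f"no bundled panel named {name!r}")
    doc = yaml.safe_load(resource.read_text())
    return _as_panel(doc)


# ---------------------------------------------------------------------------
# plate planning


def reactions_per_sample(panel: Panel) -> int:
    """Wells consumed by one fully typed sample (reactions x replicates)."""
    return len(panel.reactions) * panel.replicates


def _well_names() -> list[str]:
    return [f"{row}{col}" for row in PLATE_ROWS for col in range(1, PLATE_COLUMNS + 1)]


def plan_plates(
    panel: Panel,
    sample_ids: Sequence[str],
    controls: Sequence[tuple[str, Mapping[str, int]]] = (),
) -> list[PlateLayout]:
    """Lay out samples on 384-well plates, row-major, replicates contiguous.

    Every plate carries all control samples (known copy-number vectors), as
    in a real run where controls anchor the calibration on each plate.
    """
    if not sample_ids:
        raise ValueError("no samples to plate")
    if not panel.reactions:
        raise ValueError("panel has no reactions")
    per_sample = reactions_per_sample(panel)
    capacity = PLATE_WELLS // per_sample - len(controls)
    if capacity < 1:
        raise ValueError(
            f"panel needs {per_sample} wells/sample; a 384-well plate cannot "
            f"hold {len(controls)} controls plus one sample"
        )
    names = _well_names()
    layouts: list[PlateLayout] = []
    remaining = list(sample_ids)
    plate_no = 0
    while remaining:
        plate_no += 1
        chunk, remaining = remaining[:capacity], remaining[capacity:]
        wells: dict[str, tuple[str, str, int]] = {}
        cursor = iter(names)
        for sid in [c[0] for c in controls] + chunk:
            for reaction in panel.reactions:
                for rep in range(1, panel.replicates + 1):
                    wells[next(cursor)] = (sid, reaction.reaction_id, rep)
        layouts.append(
            PlateLayout(
                plate_id=f"plate{plate_no:02d}",
                wells=wells,
                control_samples=[(s, dict(v)) for s, v in controls],
            )
        )
    return layouts


def export_layout(layouts: Iterable[PlateLayout], path: str | Path) -> None:
    """Write plate layouts as CSV (plate, well, sample, reaction, replicate)."""
    with open(path, "w") as fh:
        fh.write("plate,well,sample,reaction,replicate\n")
        for layout in layouts:
            for well, (sid, rid, rep) in layout.wells.items():
                fh.write(f"{layout.plate_id},{well},{sid},{rid},{rep}\n")


# ---------------------------------------------------------------------------
# truth projection


def marker_truth(panel: Panel, locus_cn: Mapping[str, int]) -> dict[str, int]:
    """Expand a gene-level copy-number vector to per-assay-marker truth.

    Markers inherit the copy number of their gene; sum-rule totals are the
    sum of their components' genes; reference assays carry the panel's fixed
    reference copy number.
    """
    sums = dict(panel.sum_rules)
    out: dict[str, int] = {}
    for m in panel.markers:
        if m.is_reference:
            out[m.marker_id] = panel.reference_copy_number
        elif m.marker_id in sums:
            out[m.marker_id] = sum(
                locus_cn[panel.marker(c).gene] for c in sums[m.marker_id]
            )
        else:
            out[m.marker_id] = locus_cn[m.gene]
    return out
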