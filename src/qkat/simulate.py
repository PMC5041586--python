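"""Synthetic cohorts and multiplex qPCR plates for end-to-end testing.

The generator emulates a quadruplicate 384-well relative-quantification run:

* genotypes are drawn by sampling two haplotypes i.i.d. from a gene-content
  library, proportional to haplotype frequency (a random-mating cohort);
* each well's Cq follows the log-linear qPCR model — Cq drops by one cycle
  per doubling of starting template at perfect efficiency, and by
  1/log2(1+E) cycles otherwise;
* a per-sample DNA-concentration offset (log2 scale) shifts all of a
  sample's Cq values together, as mis-quantified DNA input does; it cancels
  in ΔCq because target and reference share the well;
* per-channel Gaussian noise with SD sigma_delta_cq/sqrt(2) gives replicate
  ΔCq values an SD of sigma_delta_cq;
* zero-copy targets do not amplify (optionally they amplify "leakily" at
  38-42 cycles, to exercise the late-Cq zero-call rule);
* allele-dropout events remove one copy's contribution from a single assay
  of a gene, the signature of a rare SNP under a primer/probe: the second
  assay of the pair still sees every copy, so the calls disagree.

Default noise levels are fixed at the conditions of a validated assay:
sigma_delta_cq = 0.15 cycles (inside the >99.6 % discrimination tier, which
requires cluster SDs below 0.167) and a DNA-concentration spread of 0.5 on
the log2 scale (about ±40 % around the nominal 5 ng input).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .haplotypes import HaplotypeLibrary
from .io import NO_AMPLIFICATION, WellRecord
from .panel import Panel, PlateLayout, marker_truth, plan_plates

DEFAULT_SIGMA_DELTA_CQ = 0.15
DEFAULT_SIGMA_CONCENTRATION = 0.5
DEFAULT_TARGET_BASE_CQ = 24.0
DEFAULT_REFERENCE_BASE_CQ = 22.0


@dataclass
class NoiseModel:
    """Noise and assay-behaviour parameters for plate simulation.

    ``dropout_events`` lists (sample_id, marker_id) pairs: that assay sees
    one copy fewer than the sample truly carries at the gene.
    """

    sigma_delta_cq: float = DEFAULT_SIGMA_DELTA_CQ
    sigma_concentration: float = DEFAULT_SIGMA_CONCENTRATION
    efficiency: dict[str, float] = field(default_factory=dict)
    base_cq: dict[str, float] = field(default_factory=dict)
    dropout_events: list[tuple[str, str]] = field(default_factory=list)
    leaky_zero: bool = False

    def __post_init__(self) -> None:
        if self.sigma_delta_cq < 0 or self.sigma_concentration < 0:
            raise ValueError("noise SDs must be nonnegative")
        for marker, cq in self.base_cq.items():
            if not 10 < cq < 35:
                raise ValueError(f"base Cq {cq} for {marker} outside (10, 35)")

    def base_for(self, marker_id: str, is_reference: bool) -> float:
        return self.base_cq.get(
            marker_id,
            DEFAULT_REFERENCE_BASE_CQ if is_reference else DEFAULT_TARGET_BASE_CQ,
        )

    def efficiency_for(self, marker_id: str) -> float:
        return self.efficiency.get(marker_id, 1.0)


@dataclass
class TruthSample:
    sample_id: str
    haplotype_ids: tuple[str, str] | None
    locus_cn: dict[str, int]


@dataclass
class TruthSet:
    """Ground truth for a simulated cohort: haplotype pairs and genotypes."""

    marker_order: tuple[str, ...]
    samples: list[TruthSample]

    @classmethod
    def from_genotypes(cls, genotypes: Mapping[str, Mapping[str, int]]) -> "TruthSet":
        sids = list(genotypes)
        order = tuple(genotypes[sids[0]]) if sids else ()
        return cls(
            marker_order=order,
            samples=[TruthSample(s, None, dict(genotypes[s])) for s in sids],
        )

    def genotype_vector(self, sample_id: str) -> tuple[int, ...]:
        s = next(x for x in self.samples if x.sample_id == sample_id)
        return tuple(s.locus_cn[m] for m in self.marker_order)


def fixture_library() -> HaplotypeLibrary:
    """The bundled gene-content haplotype library (synthetic frequencies)."""
    from .io import read_haplotype_library

    with resources.as_file(
        resources.files("qkat.data").joinpath("haplotype_library.csv")
    ) as path:
        return read_haplotype_library(path)


def default_controls(
    library: HaplotypeLibrary | None = None,
) -> list[tuple[str, dict[str, int]]]:
    """Three known-copy-number control genotypes (gene-level vectors).

    CTRL_A and CTRL_B are homozygous/compound group-A and group-B genotypes;
    CTRL_AB is the heterozygote.  Together they anchor every panel marker at
    a nonzero copy number.
    """
    library = library or fixture_library()
    pairs = {
        "CTRL_A": ("cA01", "cA01"),
        "CTRL_B": ("cB01", "cB02"),
        "CTRL_AB": ("cA01", "cB01"),
    }
    out = []
    for sid, (h1, h2) in pairs.items():
        g = {
            m: library[h1].signature[i] + library[h2].signature[i]
            for i, m in enumerate(library.marker_order)
        }
        out.append((sid, g))
    return out


def simulate_cohort(
    library: HaplotypeLibrary,
    n_samples: int,
    seed: int,
    id_prefix: str = "S",
) -> TruthSet:
    """Draw a cohort of genotypes by sampling haplotype pairs from the library."""
    if len(library) == 0:
        raise ValueError("cannot sample from an empty library")
    freqs = np.array([h.frequency for h in library], dtype=float)
    total = freqs.sum()
    if total <= 0:
        raise ValueError("library frequencies must sum to a positive value")
    probs = freqs / total
    rng = np.random.default_rng(seed)
    haps = list(library)
    samples = []
    for i in range(n_samples):
        i1, i2 = rng.choice(len(haps), size=2, p=probs)
        h1, h2 = haps[i1], haps[i2]
        locus_cn = {
            m: h1.signature[j] + h2.signature[j]
            for j, m in enumerate(library.marker_order)
        }
        samples.append(
            TruthSample(f"{id_prefix}{i + 1:04d}", (h1.haplotype_id, h2.haplotype_id), locus_cn)
        )
    return TruthSet(marker_order=library.marker_order, samples=samples)


def simulate_plate(
    truth: TruthSet,
    panel: Panel,
    noise: NoiseModel | None = None,
    controls: Sequence[tuple[str, Mapping[str, int]]] | None = None,
    seed: int = 0,
) -> tuple[list[WellRecord], list[PlateLayout]]:
    """Simulate Cq wells for a cohort on 384-well plates.

    Returns the well records (what a cycler export would contain) and the
    plate layouts used.  Controls default to the bundled three; pass ``()``
    to simulate without controls.
    """
    noise = noise or NoiseModel()
    if controls is None:
        controls = default_controls()
    layouts = plan_plates(panel, [s.sample_id for s in truth.samples], controls)

    genotypes: dict[str, Mapping[str, int]] = {
        s.sample_id: s.locus_cn for s in truth.samples
    }
    genotypes.update({sid: g for sid, g in controls})
    marker_cn = {sid: marker_truth(panel, g) for sid, g in genotypes.items()}
    dropouts = set(noise.dropout_events)

    master = np.random.default_rng(seed)
    conc_rng = np.random.default_rng(master.integers(2**31))
    conc_offset = {
        sid: (conc_rng.normal(0.0, noise.sigma_concentration)
              if noise.sigma_concentration > 0 else 0.0)
        for sid in genotypes
    }
    ref_scale = panel.reference_copy_number
    sigma_channel = noise.sigma_delta_cq / math.sqrt(2.0)

    wells: list[WellRecord] = []
    for layout in layouts:
        rng = np.random.default_rng(master.integers(2**31))
        for well, (sid, rid, rep) in layout.wells.items():
            reaction = panel.reaction(rid)
            record = WellRecord(layout.plate_id, well, sid, rid, rep)
            for marker_id in reaction.all_markers:
                assay = panel.marker(marker_id)
                cn = marker_cn[sid][marker_id]
                if (sid, marker_id) in dropouts:
                    cn = max(cn - 1, 0)
                eps = rng.normal(0.0, sigma_channel) if sigma_channel > 0 else 0.0
                e = noise.efficiency_for(marker_id)
                slope = 1.0 / math.log2(1.0 + e)
                base = noise.base_for(marker_id, assay.is_reference)
                if cn == 0:
                    if noise.leaky_zero:
                        record.cq_by_marker[marker_id] = float(rng.uniform(37.0, 40.0))
                    else:
                        record.cq_by_marker[marker_id] = NO_AMPLIFICATION
                    continue
                cq = base - slope * (math.log2(cn / ref_scale) + conc_offset[sid]) + eps
                record.cq_by_marker[marker_id] = float(cq)
            wells.append(record)
    return wells, layouts
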