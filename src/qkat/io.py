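"""Readers and writers for the plain-text formats of the pipeline.

Formats (all comma-separated, dot-decimal, UTF-8):

* **Cq export** — one row per well and channel, emulating a real-time-cycler
  export: ``plate,well,sample,reaction,replicate,channel,cq``.  The channel
  column may carry either a dye name (resolved through the panel's reaction
  definition) or a marker id.  Blank, ``-``, ``NA`` or ``>``-prefixed cells,
  and any Cq above the no-amplification threshold (default 40 cycles), are
  read as :data:`NO_AMPLIFICATION`.
* **Copy-number table** — one row per sample x marker with calculated and
  predicted copy number, confidence, z-score, QC flags and replicate count.
* **Haplotype library** — ``haplotype_id,signature,count,frequency,
  cen_motif,tel_motif`` with hyphen-delimited signatures; an optional
  ``# marker_order:`` comment line pins the marker order.
* **Haplotype results** — the three result files: all candidate pairs per
  sample, best pairs only, and a log of unresolved samples with their
  single-haplotype matches.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .haplotypes import Haplotype, HaplotypeLibrary, Resolution, ResolutionStatus
from .panel import Panel

logger = logging.getLogger(__name__)

#: Default Cq ceiling: anything later is treated as no amplification.
NO_AMPLIFICATION_CQ = 40.0

MAX_CQ = 45.0

#: Documented QC flag vocabulary for copy-number tables.
QC_FLAGS = (
    "REF_FAIL",
    "REF_CQ_HIGH",
    "OUTLIER_REMOVED",
    "ZERO_CANDIDATE",
    "ZERO_CALL",
    "TOO_FEW_REPLICATES",
    "NO_CALIBRATOR",
    "PAIR_DISCORDANT",
    "RULE_VIOLATION",
    "AMBIGUOUS_MODE",
    "LOW_N",
    "SD_UNDEFINED",
)


class _NoAmplification:
    """Singleton marking a well/channel with no Cq (no amplification)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_AMPLIFICATION"


NO_AMPLIFICATION = _NoAmplification()

CqValue = float | _NoAmplification


class CqExportError(ValueError):
    """Raised for malformed Cq export files."""


@dataclass
class WellRecord:
    """One well's Cq values, keyed by marker id."""

    plate_id: str
    well: str
    sample_id: str
    reaction_id: str
    replicate_index: int
    cq_by_marker: dict[str, CqValue] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Cq export


def _parse_cq(cell: str, no_amp_cq: float) -> CqValue:
    cell = cell.strip()
    if cell in ("", "-", "NA", "NaN", "nan") or cell.startswith(">"):
        return NO_AMPLIFICATION
    value = float(cell)
    if value > no_amp_cq:
        return NO_AMPLIFICATION
    if not 0 < value <= MAX_CQ:
        raise CqExportError(f"Cq value {value} outside (0, {MAX_CQ}]")
    return value


def read_cq_export(
    path: str | Path, panel: Panel, no_amp_cq: float = NO_AMPLIFICATION_CQ
) -> list[WellRecord]:
    """Parse a Cq export CSV into one WellRecord per well.

    The ``channel`` column is resolved to a marker through the well's
    reaction (dye names are reaction-local); marker ids are accepted
    directly.  Duplicate (well, marker) rows and channels absent from the
    named reaction are errors.
    """
    records: dict[tuple[str, str], WellRecord] = {}
    rep_counter: dict[tuple[str, str], int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"plate", "well", "sample", "reaction", "channel", "cq"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise CqExportError(f"missing columns: {sorted(missing)}")
        for row in reader:
            rid = row["reaction"]
            try:
                reaction = panel.reaction(rid)
            except KeyError:
                raise CqExportError(f"unknown reaction {rid!r} in {path}") from None
            label = row["channel"].strip()
            marker_ids = reaction.all_markers
            if label in marker_ids:
                marker_id = label
            else:
                by_channel = {panel.marker(m).channel: m for m in marker_ids}
                if label not in by_channel:
                    raise CqExportError(
                        f"channel {label!r} not in reaction {rid!r} "
                        f"(expected one of {sorted(by_channel)} or a marker id)"
                    )
                marker_id = by_channel[label]
            key = (row["plate"], row["well"])
            if key not in records:
                rep_key = (row["sample"], rid)
                rep = row.get("replicate", "").strip() if "replicate" in row else ""
                if rep:
                    replicate = int(rep)
                else:
                    rep_counter[rep_key] = rep_counter.get(rep_key, 0) + 1
                    replicate = rep_counter[rep_key]
                records[key] = WellRecord(
                    plate_id=row["plate"],
                    well=row["well"],
                    sample_id=row["sample"],
                    reaction_id=rid,
                    replicate_index=replicate,
                )
            record = records[key]
            if marker_id in record.cq_by_marker:
                raise CqExportError(f"duplicate Cq for well {key} marker {marker_id}")
            record.cq_by_marker[marker_id] = _parse_cq(row["cq"], no_amp_cq)
    return list(records.values())


def write_cq_export(wells: Iterable[WellRecord], path: str | Path, panel: Panel) -> None:
    """Write well records in the Cq export format (round-trips bit-exactly)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plate", "well", "sample", "reaction", "replicate", "channel", "cq"])
        for w in wells:
            for marker_id, cq in w.cq_by_marker.items():
                cell = "" if cq is NO_AMPLIFICATION else repr(float(cq))
                writer.writerow(
                    [w.plate_id, w.well, w.sample_id, w.reaction_id,
                     w.replicate_index, panel.marker(marker_id).channel or marker_id, cell]
                )


# ---------------------------------------------------------------------------
# copy-number table

CN_TABLE_COLUMNS = [
    "sample_id", "marker_id", "calculated_cn", "predicted_cn",
    "confidence", "z_score", "qc_flags", "n_replicates_used",
]


def write_copy_number_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, columns=[c for c in CN_TABLE_COLUMNS if c in table.columns])


def read_copy_number_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "marker_id": str})
    df["qc_flags"] = df["qc_flags"].fillna("")
    return df


# ---------------------------------------------------------------------------
# haplotype library


def read_haplotype_library(
    path: str | Path, marker_order: Sequence[str] | None = None
) -> HaplotypeLibrary:
    """Load a haplotype library CSV, validating signatures against the marker order.

    The marker order is taken from the file's ``# marker_order:`` comment if
    present; an explicitly passed order must agree with it.
    """
    file_order: tuple[str, ...] | None = None
    rows: list[dict[str, str]] = []
    with open(path, newline="") as fh:
        header_lines = []
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if body.lower().startswith("marker_order:"):
                    file_order = tuple(
                        t.strip() for t in body.split(":", 1)[1].split(",") if t.strip()
                    )
                continue
            header_lines.append(line)
        reader = csv.DictReader(header_lines)
        rows = list(reader)

    if marker_order is not None and file_order is not None:
        if tuple(marker_order) != file_order:
            raise HaplotypeLibraryMismatch(
                f"library marker order {file_order} != expected {tuple(marker_order)}"
            )
    order = tuple(marker_order) if marker_order is not None else file_order
    haplotypes = []
    for row in rows:
        signature = tuple(int(x) for x in row["signature"].split("-"))
        if order is None:
            order = tuple(f"m{i+1}" for i in range(len(signature)))
        haplotypes.append(
            Haplotype(
                haplotype_id=row["haplotype_id"],
                signature=signature,
                count=int(row.get("count") or 0),
                frequency=float(row.get("frequency") or 0.0),
                cen_motif=row.get("cen_motif", "") or "",
                tel_motif=row.get("tel_motif", "") or "",
            )
        )
    if order is None:
        order = tuple(marker_order or ())
    return HaplotypeLibrary(order, haplotypes)


class HaplotypeLibraryMismatch(ValueError):
    pass


def write_haplotype_library(library: HaplotypeLibrary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# marker_order: " + ",".join(library.marker_order) + "\n")
        writer = csv.writer(fh)
        writer.writerow(["haplotype_id", "signature", "count", "frequency", "cen_motif", "tel_motif"])
        for h in library:
            writer.writerow(
                [h.haplotype_id, "-".join(str(c) for c in h.signature),
                 h.count, repr(h.frequency), h.cen_motif, h.tel_motif]
            )


# ---------------------------------------------------------------------------
# haplotype results (three files)

PAIR_COLUMNS = [
    "sample_id", "markersig", "haplotype_1", "haplotype_2",
    "frequency_1", "frequency_2", "combined_frequency",
]
LOG_COLUMNS = ["sample_id", "markersig", "single_matches", "note"]

HAPLOTYPE_RESULT_FILES = {
    "pairs": "haplotype_pairs.csv",
    "best": "haplotype_best_pairs.csv",
    "log": "haplotype_unresolved_log.csv",
}


def _sig_string(copies) -> str:
    from .haplotypes import markersig

    try:
        return markersig(copies)
    except ValueError:
        return markersig(copies, delimiter="-")


def write_haplotype_outputs(
    results: Iterable[Resolution], out_dir: str | Path
) -> dict[str, Path]:
    """Write the three haplotype result files.

    File 1 lists every candidate pair per sample with per-haplotype and
    combined frequencies; file 2 only the pair(s) with the highest combined
    frequency; file 3 (log) the unresolved samples with their possible
    single haplotypes.  Every sample lands in exactly one of files 2 and 3.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: out_dir / v for k, v in HAPLOTYPE_RESULT_FILES.items()}

    def pair_row(res: Resolution, pair) -> list:
        return [
            res.sample_id, _sig_string(res.genotype),
            pair.haplotype_1.haplotype_id, pair.haplotype_2.haplotype_id,
            repr(pair.haplotype_1.frequency), repr(pair.haplotype_2.frequency),
            repr(pair.combined_frequency),
        ]

    with open(paths["pairs"], "w", newline="") as f_all, \
            open(paths["best"], "w", newline="") as f_best, \
            open(paths["log"], "w", newline="") as f_log:
        w_all, w_best, w_log = csv.writer(f_all), csv.writer(f_best), csv.writer(f_log)
        w_all.writerow(PAIR_COLUMNS)
        w_best.writerow(PAIR_COLUMNS)
        w_log.writerow(LOG_COLUMNS)
        for res in results:
            if res.status is ResolutionStatus.RESOLVED:
                for pair in res.pairs:
                    w_all.writerow(pair_row(res, pair))
                for pair in res.best_pairs:
                    w_best.writerow(pair_row(res, pair))
            else:
                singles = ";".join(h.haplotype_id for h in res.single_matches)
                note = "no haplotype pair sums to genotype" if res.single_matches else "no library match"
                w_log.writerow([res.sample_id, _sig_string(res.genotype), singles, note])
    return paths


# ---------------------------------------------------------------------------
# truth sets (synthetic-cohort ground truth)


def write_truth_set(truth, path: str | Path) -> None:
    """Write a simulated cohort's ground truth (one row per sample)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "haplotype_1", "haplotype_2", *truth.marker_order])
        for s in truth.samples:
            h1, h2 = s.haplotype_ids if s.haplotype_ids else ("", "")
            writer.writerow([s.sample_id, h1, h2, *[s.locus_cn[m] for m in truth.marker_order]])


def read_truth_set(path: str | Path):
    from .simulate import TruthSample, TruthSet

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        marker_order = tuple(header[3:])
        samples = []
        for row in reader:
            sid, h1, h2, *cns = row
            samples.append(
                TruthSample(
                    sample_id=sid,
                    haplotype_ids=(h1, h2) if h1 else None,
                    locus_cn=dict(zip(marker_order, map(int, cns))),
                )
            )
    return TruthSet(marker_order=marker_order, samples=samples)
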