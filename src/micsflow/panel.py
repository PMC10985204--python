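"""Antibody panel registry and staining-cycle planning.

The immunophenotyping panel is a table of fluorochrome-conjugated
antibodies (antigen, clone, reciprocal dilution, order number, primary
fluorochrome with tested alternate conjugates, vendor).  Cyclic staining
instruments image a small number of fluorescence channels per cycle, so a
panel of ~120 antibodies is spread over many cycles.  Two spectral-overlap
rules constrain which antibodies may share a cycle:

R1
    FITC- and PE-conjugated antibodies marking the same cell type or state
    must not be co-cycled (their emission spectra overlap enough to create
    false-positive signal on co-stained cells).
R2
    A FITC antibody against a strongly expressed antigen must not be
    co-cycled with a PE antibody against a weakly expressed antigen (FITC
    spillover would swamp the weak PE signal).

A nuclear counterstain (DAPI) is re-applied at a fixed cycle interval
(every eighth antibody cycle by default) to compensate for washout.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

FLUOROCHROMES = ("FITC", "PE", "APC")

#: Antigen aliases applied when counting unique antigen identities.  The
#: panel carries two PD-L1 clones and marks CD15 both directly and via the
#: SSEA-1 epitope, so 121 antibody entries address 118 distinct antigens.
DEFAULT_ANTIGEN_ALIASES: dict[str, str] = {
    "SSEA-1 (CD15)": "CD15",
    "PD-L1 1": "PD-L1",
    "PD-L1 2": "PD-L1",
}


class PanelError(ValueError):
    """Raised for malformed panel files or infeasible cycle plans."""


@dataclass(frozen=True)
class PanelEntry:
    """One antibody conjugate row of the panel table."""

    antigen: str
    clone: str
    dilution: float  # reciprocal dilution factor: 50 means 1:50
    order_no: str
    primary_fluor: str
    alternate_fluors: frozenset[str] = frozenset()
    vendor: str = ""
    expression_strength: str = "unknown"  # {weak, strong, unknown}
    target_classes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.antigen:
            raise PanelError("antigen must be nonempty")
        if self.dilution <= 0:
            raise PanelError(f"{self.antigen}: dilution must be positive")
        if self.primary_fluor not in FLUOROCHROMES:
            raise PanelError(
                f"{self.antigen}: unknown fluorochrome {self.primary_fluor!r}"
            )
        if self.primary_fluor in self.alternate_fluors:
            raise PanelError(
                f"{self.antigen}: primary fluorochrome repeated in alternates"
            )
        if self.expression_strength not in ("weak", "strong", "unknown"):
            raise PanelError(
                f"{self.antigen}: bad expression_strength {self.expression_strength!r}"
            )


@dataclass
class Panel:
    """Ordered collection of panel entries with unique (antigen, clone)."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        keys = [(e.antigen, e.clone) for e in self.entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise PanelError(f"duplicate (antigen, clone) pairs: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


_FLUOR_RE = re.compile(r"^\s*(\w+)\s*(?:\(([^)]*)\))?\s*$")

REQUIRED_COLUMNS = ("Antigen", "Clone", "Dilution", "OrderNo", "Fluorochrome", "Company")


def _parse_fluor_field(text: str, row_label: str) -> tuple[str, frozenset[str]]:
    m = _FLUOR_RE.match(text)
    if m is None:
        raise PanelError(f"row {row_label}: unparseable fluorochrome field {text!r}")
    primary = m.group(1).strip()
    alternates = frozenset(
        a.strip() for a in (m.group(2) or "").split(",") if a.strip()
    )
    return primary, alternates


def load_panel(
    path: str | Path,
    *,
    expression_strengths: Mapping[str, str] | None = None,
    target_classes: Mapping[str, Iterable[str]] | None = None,
) -> Panel:
    """Load a panel from CSV, preserving row order.

    The CSV must carry the columns ``Antigen, Clone, Dilution, OrderNo,
    Fluorochrome, Company``; alternate conjugates are listed in
    parentheses inside the Fluorochrome field, e.g. ``FITC (APC, PE)``.
    ``expression_strengths`` and ``target_classes`` attach optional
    cycle-planning metadata keyed by antigen.
    """
    strengths = dict(expression_strengths or {})
    classes = dict(target_classes or {})
    entries: list[PanelEntry] = []
    with open(path, newline="", encoding="utf-8") as f:
        reader = csv.DictReader(f)
        missing = [c for c in REQUIRED_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise PanelError(f"panel CSV missing columns: {missing}")
        for i, row in enumerate(reader, start=2):
            label = f"{i} ({row.get('Antigen', '?')})"
            try:
                dilution = float(row["Dilution"])
            except (TypeError, ValueError):
                raise PanelError(
                    f"row {label}: unparseable dilution {row.get('Dilution')!r}"
                ) from None
            primary, alternates = _parse_fluor_field(row["Fluorochrome"], label)
            antigen = row["Antigen"].strip()
            entries.append(
                PanelEntry(
                    antigen=antigen,
                    clone=row["Clone"].strip(),
                    dilution=dilution,
                    order_no=row["OrderNo"].strip(),
                    primary_fluor=primary,
                    alternate_fluors=alternates,
                    vendor=row["Company"].strip(),
                    expression_strength=strengths.get(antigen, "unknown"),
                    target_classes=frozenset(classes.get(antigen, ())),
                )
            )
    return Panel(entries)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to the CSV interchange format (round-trips load_panel)."""
    with open(path, "w", newline="", encoding="utf-8") as f:
        w = csv.writer(f)
        w.writerow(REQUIRED_COLUMNS)
        for e in panel:
            fluor = e.primary_fluor
            if e.alternate_fluors:
                fluor += f" ({', '.join(sorted(e.alternate_fluors))})"
            dil = int(e.dilution) if float(e.dilution).is_integer() else e.dilution
            w.writerow([e.antigen, e.clone, dil, e.order_no, fluor, e.vendor])


def bundled_panel_path() -> Path:
    """Path to the packaged immuno-oncology panel table (121 antibodies)."""
    return Path(resources.files("micsflow.data") / "panel_table1.csv")


def load_bundled_panel(**kwargs) -> Panel:
    return load_panel(bundled_panel_path(), **kwargs)


def panel_counts(
    panel: Panel, aliases: Mapping[str, str] | None = None
) -> dict[str, int]:
    """Summary arithmetic over a panel.

    Returns antibody count, unique antigen count (after alias merging),
    alternate-conjugate count, and total validated conjugates
    (primary + alternates).
    """
    alias_map = DEFAULT_ANTIGEN_ALIASES if aliases is None else dict(aliases)
    canonical = {alias_map.get(e.antigen, e.antigen) for e in panel}
    n_alt = sum(len(e.alternate_fluors) for e in panel)
    return {
        "n_antibodies": len(panel),
        "n_unique_antigens": len(canonical),
        "n_alternate_conjugates": n_alt,
        "n_total_conjugates": len(panel) + n_alt,
    }


@dataclass
class Cycle:
    """One staining cycle: at most one antibody per fluorescence channel."""

    index: int  # 1-based
    assignments: dict[str, PanelEntry] = field(default_factory=dict)
    dapi_restain: bool = False


@dataclass
class CyclePlan:
    cycles: list[Cycle]
    dapi_interval: int = 8

    def entry_count(self) -> int:
        return sum(len(c.assignments) for c in self.cycles)

    def to_rows(self) -> list[dict]:
        rows = []
        for c in self.cycles:
            for channel in sorted(c.assignments):
                e = c.assignments[channel]
                rows.append(
                    {
                        "cycle_index": c.index,
                        "channel": channel,
                        "antigen": e.antigen,
                        "clone": e.clone,
                        "dapi_restain": c.dapi_restain,
                    }
                )
        return rows

    def write_csv(self, path: str | Path) -> None:
        rows = self.to_rows()
        with open(path, "w", newline="", encoding="utf-8") as f:
            w = csv.DictWriter(
                f, fieldnames=["cycle_index", "channel", "antigen", "clone", "dapi_restain"]
            )
            w.writeheader()
            w.writerows(rows)


def _violates_rules(entry: PanelEntry, cycle: Cycle) -> bool:
    """Check spectral-overlap rules R1/R2 for adding `entry` to `cycle`."""
    for other in cycle.assignments.values():
        pair = {entry.primary_fluor, other.primary_fluor}
        if pair != {"FITC", "PE"}:
            continue
        # R1: FITC and PE marking a shared cell type/state
        if entry.target_classes & other.target_classes:
            return True
        # R2: strong FITC with weak PE
        fitc, pe = (entry, other) if entry.primary_fluor == "FITC" else (other, entry)
        if fitc.expression_strength == "strong" and pe.expression_strength == "weak":
            return True
    return False


def plan_cycles(
    panel: Panel,
    channels: Iterable[str] = FLUOROCHROMES,
    dapi_interval: int = 8,
) -> CyclePlan:
    """Assign every panel entry to a staining cycle by greedy first fit.

    Entries are taken in panel order and placed into the earliest cycle
    whose channel is free and where neither spectral rule is violated.
    Deterministic for a fixed panel order; not guaranteed minimal.
    """
    channel_set = set(channels)
    bad = [e.antigen for e in panel if e.primary_fluor not in channel_set]
    if bad:
        raise PanelError(f"entries with fluorochrome outside channels: {bad}")
    if dapi_interval < 1:
        raise PanelError("dapi_interval must be a positive integer")

    cycles: list[Cycle] = []
    for entry in panel:
        placed = False
        for cycle in cycles:
            if entry.primary_fluor in cycle.assignments:
                continue
            if _violates_rules(entry, cycle):
                continue
            cycle.assignments[entry.primary_fluor] = entry
            placed = True
            break
        if not placed:
            cycle = Cycle(index=len(cycles) + 1)
            cycle.assignments[entry.primary_fluor] = entry
            cycles.append(cycle)
    for cycle in cycles:
        cycle.dapi_restain = cycle.index % dapi_interval == 0
    return CyclePlan(cycles=cycles, dapi_interval=dapi_interval)


def check_plan(plan: CyclePlan, panel: Panel) -> list[str]:
    """Independent validity check of a cycle plan; returns violation messages.

    Verifies channel exclusivity, rules R1/R2, completeness (every panel
    entry exactly once), and the DAPI restain interval.  Kept separate
    from the planner so planner bugs cannot hide.
    """
    problems: list[str] = []
    seen: dict[tuple[str, str], int] = {}
    for cycle in plan.cycles:
        by_channel: dict[str, list[PanelEntry]] = {}
        for channel, e in cycle.assignments.items():
            by_channel.setdefault(channel, []).append(e)
            if channel != e.primary_fluor:
                problems.append(
                    f"cycle {cycle.index}: {e.antigen} assigned to {channel} "
                    f"but conjugated to {e.primary_fluor}"
                )
            seen[(e.antigen, e.clone)] = seen.get((e.antigen, e.clone), 0) + 1
        entries = list(cycle.assignments.values())
        for i, a in enumerate(entries):
            for b in entries[i + 1 :]:
                if {a.primary_fluor, b.primary_fluor} != {"FITC", "PE"}:
                    continue
                if a.target_classes & b.target_classes:
                    problems.append(
                        f"cycle {cycle.index}: R1 violation {a.antigen}/{b.antigen}"
                    )
                fitc, pe = (a, b) if a.primary_fluor == "FITC" else (b, a)
                if fitc.expression_strength == "strong" and pe.expression_strength == "weak":
                    problems.append(
                        f"cycle {cycle.index}: R2 violation {fitc.antigen}/{pe.antigen}"
                    )
        expected = cycle.index % plan.dapi_interval == 0
        if cycle.dapi_restain != expected:
            problems.append(f"cycle {cycle.index}: dapi_restain should be {expected}")
    for e in panel:
        n = seen.get((e.antigen, e.clone), 0)
        if n != 1:
            problems.append(f"{e.antigen} ({e.clone}) appears {n} times")
    return problems
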