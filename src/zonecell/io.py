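"""Reading and writing the plain-text formats used by the tool.

Pattern tables are small delimited text files (comma, tab or whitespace;
``#`` starts a comment) with columns ``id d1 d2 phi [symmetry]`` — the
layout of a printed zonal-data table.  Solutions are written as a ranked
delimited table plus an optional JSON run record carrying the full
per-pattern indexing evidence and the configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

from .patterns import ZonePattern
from .search import CandidateSolution, ScanConfig, SearchResult
from .zones import MatchWeights

__all__ = [
    "read_pattern_table",
    "write_pattern_table",
    "write_solutions",
    "read_solutions",
    "write_run_record",
    "normalize_symmetry",
]

_SYMMETRY_ALIASES = {
    "": "auto", "auto": "auto", "-": "auto",
    "p1": "p1", "1": "p1",
    "pmm": "pmm", "2mm": "pmm", "mm": "pmm", "2": "pmm", "pmm2": "pmm",
    "cmm": "cmm", "c2mm": "cmm",
    "p4": "p4", "4": "p4", "4mm": "p4", "p4mm": "p4",
    "p6": "p6", "6": "p6", "6mm": "p6", "p6mm": "p6",
}


def normalize_symmetry(label: str) -> str:
    """Map a table symmetry string (e.g. ``2mm``, ``4``) onto the internal
    plane-group labels; unknown strings raise."""
    key = label.strip().lower().replace("*", "")
    if key not in _SYMMETRY_ALIASES:
        raise ValueError(f"unknown symmetry label {label!r}")
    return _SYMMETRY_ALIASES[key]


def _split(line: str) -> list[str]:
    line = line.split("#", 1)[0].strip()
    if not line:
        return []
    for sep in (",", "\t"):
        if sep in line:
            return [f.strip() for f in line.split(sep)]
    return line.split()


def read_pattern_table(path: str | Path) -> list[ZonePattern]:
    """Read a pattern table; malformed rows are reported with line numbers."""
    path = Path(path)
    patterns: list[ZonePattern] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        fields = _split(raw)
        if not fields:
            continue
        if fields[0].lower() in ("id", "no", "no.", "pattern"):
            continue  # header row
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected 'id d1 d2 phi [symmetry]', got {raw!r}")
        pid = fields[0]
        if pid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate pattern id {pid!r}")
        try:
            d1, d2, phi = (float(x) for x in fields[1:4])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        sym = normalize_symmetry(fields[4]) if len(fields) > 4 else "auto"
        try:
            patterns.append(ZonePattern(pid, d1, d2, phi, sym))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        seen.add(pid)
    if not patterns:
        raise ValueError(f"{path}: no patterns")
    return patterns


def write_pattern_table(patterns: Sequence[ZonePattern], path: str | Path) -> None:
    lines = ["# id\td1\td2\tphi\tsymmetry"]
    for p in patterns:
        lines.append(f"{p.pattern_id}\t{p.d1:.4f}\t{p.d2:.4f}\t{p.phi:.3f}\t{p.symmetry}")
    Path(path).write_text("\n".join(lines) + "\n")


_SOLUTION_FIELDS = (
    "rank", "R", "a", "b", "c", "alpha", "beta", "gamma", "volume",
    "centring", "conv_a", "conv_b", "conv_c", "conv_alpha", "conv_beta",
    "conv_gamma", "conv_volume",
)


def write_solutions(solutions: Sequence[CandidateSolution], path: str | Path) -> None:
    """Write ranked solutions (reduced + conventional settings) as TSV."""
    lines = ["# " + "\t".join(_SOLUTION_FIELDS)]
    for rank, s in enumerate(solutions, start=1):
        red = s.reduced_cell
        row = [str(rank), f"{s.r:.4f}"] + [f"{x:.4f}" for x in red.parameters] + [f"{red.volume:.2f}"]
        if s.conventional is not None:
            conv = s.conventional
            row += [conv.centring] + [f"{x:.4f}" for x in conv.cell.parameters] + [f"{conv.volume:.2f}"]
        else:
            row += ["-"] + [""] * 7
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_solutions(path: str | Path) -> list[dict]:
    """Read back a solutions table written by :func:`write_solutions`."""
    rows = []
    for raw in Path(path).read_text().splitlines():
        fields = _split(raw)
        if not fields:
            continue
        rec: dict = {}
        for name, value in zip(_SOLUTION_FIELDS, fields):
            if name in ("rank",):
                rec[name] = int(value)
            elif name == "centring":
                rec[name] = value
            else:
                rec[name] = float(value) if value else None
        rows.append(rec)
    return rows


def write_run_record(
    result: SearchResult, config: ScanConfig, path: str | Path
) -> None:
    """JSON record of a search run: configuration, diagnostics and the full
    per-pattern indexing evidence of every returned solution."""
    cfg = dataclasses.asdict(config)
    cfg["weights"] = dataclasses.asdict(config.weights)
    record = {
        "config": cfg,
        "frame": dataclasses.asdict(result.frame),
        "n_layers": len(result.layers),
        "n_candidates": result.n_candidates,
        "n_survivors": result.n_survivors,
        "solutions": [
            {
                "rank": rank,
                "R": s.r,
                "xi": s.xi,
                "eta": s.eta,
                "volume": s.volume,
                "plane": s.plane,
                "cell": s.cell.to_dict(),
                "reduced": s.reduced_cell.to_dict(),
                "conventional": (
                    {"centring": s.conventional.centring,
                     "system": s.conventional.system,
                     **s.conventional.cell.to_dict()}
                    if s.conventional is not None else None
                ),
                "indexing": [
                    {
                        "pattern": r.pattern_id,
                        "zone": list(r.uvw),
                        "hkl_short": list(r.hkl_short),
                        "hkl_long": list(r.hkl_long),
                        "eps_ratio": r.eps_ratio,
                        "eps_angle": r.eps_angle,
                        "eps_scale": r.eps_scale,
                        "scale": r.s_p,
                        "accepted": r.accepted,
                    }
                    for r in s.results
                ],
            }
            for rank, s in enumerate(result.solutions, start=1)
        ],
    }
    Path(path).write_text(json.dumps(record, indent=1))
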