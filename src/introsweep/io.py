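"""Text formats: site tables, spectra, scan output, candidate tables, manifests.

All files are tab-separated with ``#`` comment lines, 1-based inclusive
coordinates, locale-independent formatting (6 significant digits for
probabilities, full precision for likelihood ratios). The site-file
dialect matches the classic sweep-scan layout: header ``position x n
folded``, one row per informative site, ``folded`` always 0 (the model
requires polarized data).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scan import ScanConfig, ScanResult
from .sfs import SiteTable, UnnormalizedSFS

__all__ = [
    "read_site_table",
    "write_site_table",
    "read_spectrum",
    "write_spectrum",
    "compute_spectrum",
    "read_scan",
    "write_scan",
    "write_candidates",
    "RunManifest",
]

_SITE_HEADER = ["position", "x", "n", "folded"]


def read_site_table(path: str | Path, chromosome_label: str | None = None) -> SiteTable:
    """Read a site file; reject folded rows, x = 0 rows and malformed input."""
    path = Path(path)
    positions: list[int] = []
    counts: list[int] = []
    sample_size: int | None = None
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                if [f.strip() for f in fields] != _SITE_HEADER:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {' '.join(_SITE_HEADER)!r}"
                    )
                header = fields
                continue
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            try:
                pos, x, n, folded = (int(f) for f in fields)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if folded != 0:
                raise ValueError(
                    f"{path}:{lineno}: folded={folded}; polarized data required (folded must be 0)"
                )
            if x == 0:
                raise ValueError(
                    f"{path}:{lineno}: x=0 is not an informative site; remove monomorphic rows"
                )
            if sample_size is None:
                sample_size = n
            elif n != sample_size:
                raise ValueError(
                    f"{path}:{lineno}: inconsistent sample size {n} (expected {sample_size})"
                )
            if positions and pos <= positions[-1]:
                raise ValueError(f"{path}:{lineno}: positions must be strictly increasing")
            positions.append(pos)
            counts.append(x)
    if header is None or not positions:
        raise ValueError(f"{path}: no data rows found")
    return SiteTable(
        np.array(positions), np.array(counts), int(sample_size),
        chromosome_label or path.stem,
    )


def write_site_table(table: SiteTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# chromosome: {table.chromosome_label}\n")
        fh.write("\t".join(_SITE_HEADER) + "\n")
        for pos, x in zip(table.positions, table.derived_counts):
            fh.write(f"{pos}\t{x}\t{table.sample_size}\t0\n")


def read_spectrum(path: str | Path, fixed_diffs_polarized: bool | None = None) -> UnnormalizedSFS:
    """Read a two-column ``i count`` spectrum file; missing classes are zero-filled."""
    path = Path(path)
    entries: dict[int, float] = {}
    flag_from_file: bool | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "fixed_diffs_polarized" in line:
                    flag_from_file = line.rstrip().endswith("1") or line.rstrip().endswith("true")
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns 'i count'")
            try:
                i = int(fields[0])
                w = float(fields[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed row") from None
            if i in entries:
                raise ValueError(f"{path}:{lineno}: duplicate class {i}")
            entries[i] = w
    if not entries:
        raise ValueError(f"{path}: empty spectrum file")
    n = max(entries)
    if n < 2:
        raise ValueError(f"{path}: spectrum must reach class n >= 2")
    weights = np.zeros(n + 1)
    missing = [i for i in range(n + 1) if i not in entries]
    if missing and missing != [0]:
        warnings.warn(f"{path}: classes {missing} absent; filled with zero", stacklevel=2)
    for i, w in entries.items():
        weights[i] = w
    if fixed_diffs_polarized is None:
        fixed_diffs_polarized = flag_from_file if flag_from_file is not None else True
    return UnnormalizedSFS(n, weights, fixed_diffs_polarized)


def write_spectrum(spectrum: UnnormalizedSFS, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fixed_diffs_polarized: {int(spectrum.fixed_diffs_polarized)}\n")
        for i, w in enumerate(spectrum.weights):
            fh.write(f"{i}\t{float(w)!r}\n")


def compute_spectrum(
    site_tables: list[SiteTable],
    genome_length: int | None = None,
    fixed_diffs_polarized: bool = True,
) -> UnnormalizedSFS:
    """Tally site classes genome-wide into an unnormalized spectrum.

    With ``genome_length`` the tallies become per-site probabilities
    (monomorphic sites absorbing the remaining mass implicitly).
    """
    if not site_tables:
        raise ValueError("no site tables supplied")
    n = site_tables[0].sample_size
    if any(t.sample_size != n for t in site_tables):
        raise ValueError("all site tables must share one sample size")
    weights = np.zeros(n + 1)
    for t in site_tables:
        weights[1:] += np.bincount(t.derived_counts, minlength=n + 1)[1:]
    missing = [i for i in range(1, n) if weights[i] == 0]
    if missing:
        warnings.warn(f"classes {missing} unobserved; spectrum carries zeros there", stacklevel=2)
    if genome_length is not None:
        total_sites = sum(len(t) for t in site_tables)
        if genome_length < total_sites:
            raise ValueError("genome_length smaller than the number of informative sites")
        weights = weights / genome_length
    return UnnormalizedSFS(n, weights, fixed_diffs_polarized)


_SCAN_COLUMNS = ["location", "LR", "lnCLR", "alpha", "D"]


def write_scan(result: ScanResult, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        md = result.metadata
        for key in ("theta_pi", "theta_L", "divergence_outgroup"):
            if key in md:
                fh.write(f"# {key}: {md[key]:.10g}\n")
        fh.write("\t".join(_SCAN_COLUMNS) + "\n")
        for row in result.frame.itertuples(index=False):
            fh.write(
                f"{int(row.location)}\t{float(row.LR)!r}\t{float(row.lnCLR)!r}\t"
                f"{float(row.alpha):.6g}\t{float(row.D):.6g}\n"
            )


def read_scan(path: str | Path) -> ScanResult:
    path = Path(path)
    metadata: dict = {}
    with path.open() as fh:
        rows = []
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split(":", 1)
                if len(parts) == 2:
                    try:
                        metadata[parts[0].strip()] = float(parts[1])
                    except ValueError:
                        metadata[parts[0].strip()] = parts[1].strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != _SCAN_COLUMNS:
                    raise ValueError(f"{path}:{lineno}: expected header {' '.join(_SCAN_COLUMNS)!r}")
                header_seen = True
                continue
            if len(fields) != len(_SCAN_COLUMNS):
                raise ValueError(f"{path}:{lineno}: malformed row")
            rows.append(
                {
                    "location": int(fields[0]),
                    "LR": float(fields[1]),
                    "lnCLR": float(fields[2]),
                    "alpha": float(fields[3]),
                    "D": float(fields[4]),
                }
            )
    if not rows:
        raise ValueError(f"{path}: no scan rows found")
    return ScanResult(frame=pd.DataFrame(rows), metadata=metadata)


def write_candidates(peaks, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("position\tlnCLR\talpha\tD\tvalley_bp\tvolcano_bp\tflags\n")
        for p in peaks:
            flags = ";".join(k for k, ok in p.filter_flags.items() if not ok) or "pass"
            fh.write(
                f"{p.position}\t{float(p.lnCLR)!r}\t{float(p.alpha_hat):.6g}\t"
                f"{float(p.D_hat):.6g}\t{float(p.valley_halfwidth_bp):.6g}\t"
                f"{float(p.flank_halfwidth_bp):.6g}\t{flags}\n"
            )


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically with the same build."""

    command: str
    inputs: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")


def config_as_dict(config: ScanConfig) -> dict:
    out = dataclasses.asdict(config)
    if out.get("D_grid") is not None:
        out["D_grid"] = [float(v) for v in out["D_grid"]]
    return out
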