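"""Run configuration, manifests and target-file validation for the CLI."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError
from .forward import DeuterationSeries, Segment

__all__ = ["RunConfig", "validate_hdx_file", "write_manifest", "stamp_file"]


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    """Flat, serializable record of one CLI run."""

    subcommand: str
    options: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # name -> path

    def load_file(self, path) -> None:
        """Merge a flat YAML key-value config file; CLI flags take priority,
        so file values fill only unset (None) options."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"{path}: config must be a flat mapping")
        for key, value in data.items():
            if self.options.get(key) is None:
                self.options[key] = value

    def manifest(self) -> dict:
        import importlib.metadata as md

        versions = {}
        for pkg in ("hdxens", "numpy", "scipy", "pandas", "scikit-learn",
                    "MDAnalysis"):
            try:
                versions[pkg] = md.version(pkg)
            except md.PackageNotFoundError:
                pass
        checksums = {}
        for name, path in self.inputs.items():
            if path and Path(path).exists():
                checksums[name] = _file_sha256(path)
        return {
            "subcommand": self.subcommand,
            "options": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.options.items()
            },
            "inputs": {k: str(v) for k, v in self.inputs.items()},
            "input_sha256": checksums,
            "versions": versions,
            "platform": platform.platform(),
        }

    def manifest_hash(self) -> str:
        blob = json.dumps(self.manifest(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_manifest(config: RunConfig, path) -> str:
    """Write the run manifest JSON; returns its short hash."""
    man = config.manifest()
    man["manifest_hash"] = config.manifest_hash()
    Path(path).write_text(json.dumps(man, indent=2, default=str) + "\n")
    return man["manifest_hash"]


def stamp_file(path, manifest_hash: str) -> None:
    """Prepend the tool-version / manifest-hash header to an output file."""
    from . import __version__

    p = Path(path)
    body = p.read_text()
    p.write_text(f"# hdxens {__version__} manifest={manifest_hash}\n" + body)


def validate_hdx_file(path) -> tuple[DeuterationSeries, list[str]]:
    """Parse and sanity-check a deuterated-fraction table.

    Returns the parsed series plus a list of warnings (e.g. fractions outside
    [0, 1], which noisy data may legitimately contain).  Malformed rows and
    duplicated (segment, time) entries raise :class:`InputError` with line
    numbers.  Overlapping peptides are expected and never flagged.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    lines = path.read_text().splitlines()
    rows = [
        (i + 1, ln.split())
        for i, ln in enumerate(lines)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not rows:
        raise InputError(f"{path}: empty file")
    header_no, header = rows[0]
    if header[:2] != ["segment_start", "segment_end"]:
        raise InputError(
            f"{path}:{header_no}: header must start with "
            "'segment_start segment_end'"
        )
    try:
        times = [float(c) for c in header[2:]]
    except ValueError as exc:
        raise InputError(f"{path}:{header_no}: bad time column: {exc}") from exc
    if not times:
        raise InputError(f"{path}:{header_no}: no time-point columns")
    segments: list[Segment] = []
    values = []
    seen: set[tuple[int, int]] = set()
    warnings_: list[str] = []
    for no, cells in rows[1:]:
        if len(cells) != 2 + len(times):
            raise InputError(
                f"{path}:{no}: expected {2 + len(times)} columns, got {len(cells)}"
            )
        try:
            a, b = int(cells[0]), int(cells[1])
            vals = [float(c) for c in cells[2:]]
        except ValueError as exc:
            raise InputError(f"{path}:{no}: malformed row: {exc}") from exc
        if (a, b) in seen:
            raise InputError(f"{path}:{no}: duplicated segment ({a}, {b})")
        seen.add((a, b))
        try:
            seg = Segment(a, b)
        except InputError as exc:
            raise InputError(f"{path}:{no}: {exc}") from exc
        for t, v in zip(times, vals):
            if not (0.0 <= v <= 1.0):
                warnings_.append(
                    f"{path}:{no}: fraction {v:g} at t={t:g} outside [0, 1]"
                )
        segments.append(seg)
        values.append(vals)
    return DeuterationSeries(segments, np.array(times), np.array(values)), warnings_
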