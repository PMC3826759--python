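"""INI-style run configuration.

A run is driven by a single plain-text configuration file in Windows
INI style.  Sections:

``[inputs]``
    ``tumor``, ``normal`` (alignment or fixture files), ``reference``
    (FASTA), optional ``germline_db``.
``[run]``
    ``platform`` (solid|illumina), optional ``filter`` (a read-filter
    DSL expression overriding the platform preset), ``seed``, and output
    paths ``vcf_out`` / ``dcc_out``.
``[thresholds]``
    optional overrides for any evidence or annotation threshold, keyed
    by the dataclass field names (e.g. ``min_reads_low = 4``).
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .annotate import DEFAULT_ANNOTATION, AnnotationThresholds
from .filters import PRESETS, FilterSpec, parse_filter_spec
from .genotype import DEFAULT_THRESHOLDS, EvidenceThresholds

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Malformed or incomplete configuration."""


@dataclass
class RunConfig:
    tumor_path: Path
    normal_path: Path
    reference_path: Path
    platform: str = "illumina"
    filter_spec: Optional[FilterSpec] = None
    germline_db_path: Optional[Path] = None
    vcf_out: Optional[Path] = None
    dcc_out: Optional[Path] = None
    seed: int = 0
    evidence: EvidenceThresholds = field(default_factory=EvidenceThresholds)
    annotation: AnnotationThresholds = field(default_factory=AnnotationThresholds)

    def effective_filter(self) -> FilterSpec:
        if self.filter_spec is not None:
            return self.filter_spec
        return PRESETS[self.platform]


def load_config(path: str | Path) -> RunConfig:
    """Parse an INI configuration file into a :class:`RunConfig`.

    Missing required keys and malformed values raise :class:`ConfigError`
    naming the key; INI syntax errors propagate with the line number.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    parser = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    try:
        parser.read(p)
    except configparser.Error as exc:
        raise ConfigError(f"malformed INI: {exc}") from exc

    if "inputs" not in parser:
        raise ConfigError("missing [inputs] section")
    inputs = parser["inputs"]
    for key in ("tumor", "normal", "reference"):
        if key not in inputs:
            raise ConfigError(f"missing required key [inputs] {key}")

    run = parser["run"] if "run" in parser else {}
    platform = str(run.get("platform", "illumina")).lower()
    if platform not in PRESETS:
        raise ConfigError(f"unknown platform {platform!r} (expected solid|illumina)")

    filter_spec = None
    if "filter" in run:
        filter_spec = parse_filter_spec(run["filter"])

    evidence = DEFAULT_THRESHOLDS
    annotation = DEFAULT_ANNOTATION
    if "thresholds" in parser:
        section = parser["thresholds"]
        ev_fields = {f.name for f in dataclasses.fields(EvidenceThresholds)}
        an_fields = {f.name for f in dataclasses.fields(AnnotationThresholds)}
        unknown = set(section) - ev_fields - an_fields
        if unknown:
            raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
        ev_overrides = {}
        an_overrides = {}
        for key in section:
            raw = section[key]
            if key in ev_fields:
                f = next(f for f in dataclasses.fields(EvidenceThresholds) if f.name == key)
                ev_overrides[key] = float(raw) if "float" in str(f.type) else int(raw)
            else:
                an_overrides[key] = int(raw)
        try:
            if ev_overrides:
                evidence = dataclasses.replace(evidence, **ev_overrides)
            if an_overrides:
                annotation = dataclasses.replace(annotation, **an_overrides)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid threshold override: {exc}") from exc

    def _opt_path(sec, key):
        return Path(sec[key]) if key in sec else None

    return RunConfig(
        tumor_path=Path(inputs["tumor"]),
        normal_path=Path(inputs["normal"]),
        reference_path=Path(inputs["reference"]),
        platform=platform,
        filter_spec=filter_spec,
        germline_db_path=_opt_path(inputs, "germline_db"),
        vcf_out=_opt_path(run, "vcf_out") if run else None,
        dcc_out=_opt_path(run, "dcc_out") if run else None,
        seed=int(run.get("seed", 0)) if run else 0,
        evidence=evidence,
        annotation=annotation,
    )
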