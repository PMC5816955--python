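"""YAML-backed analysis configuration.

A config file has one section per stage; keys within a section must match
the fields of the corresponding parameter set (unknown keys are rejected so
typos fail loudly).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from lbt2kit.synthio import SimConfig


@dataclass
class BulkDEParams:
    lfc_threshold: float = 2.0
    fdr_threshold: float = 0.05


@dataclass
class ScDEParams:
    lfc_threshold: float = 0.0
    fdr_threshold: float = 0.05


@dataclass
class CellCycleParams:
    refine: bool = True
    refine_corr_threshold: float = 0.3


@dataclass
class AtacParams:
    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    tss_window: int = 3000
    tss_binsize: int = 50
    top_n_peaks: int = 2000
    notch_min_depth_ratio: float = 0.5
    notch_min_width: int = 6
    notch_max_width: int = 30


@dataclass
class QpcrParams:
    reference_gene: str = "Rps11"


@dataclass
class AnalysisConfig:
    simulate: SimConfig = field(default_factory=SimConfig)
    bulk_de: BulkDEParams = field(default_factory=BulkDEParams)
    sc_de: ScDEParams = field(default_factory=ScDEParams)
    cellcycle: CellCycleParams = field(default_factory=CellCycleParams)
    atac: AtacParams = field(default_factory=AtacParams)
    qpcr: QpcrParams = field(default_factory=QpcrParams)


def _build(cls, data: dict, section: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown keys in section {section!r}: {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path: str | Path | None) -> AnalysisConfig:
    """Load (or default) the analysis configuration; unknown keys rejected."""
    if path is None:
        return AnalysisConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sections = {f.name: f.default_factory for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - set(sections)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for name, factory in sections.items():
        if name in data:
            kwargs[name] = _build(type(factory()), data[name] or {}, name)
    cfg = AnalysisConfig(**kwargs)
    cfg.simulate.validate()
    return cfg
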