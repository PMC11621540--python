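"""Signature sets and analysis configuration.

The signature set maps each named TME feature (well-differentiated,
proliferative, invasive tumor states; B cell, T cell, fibroblast/CAF,
macrophage microenvironment states) to a gene list.  The gene lists that
ship with the package are synthetic stand-ins for study-specific curated
lists and are expected to be replaced by users working with real sections;
the T-cell state module sets (naive, cytotoxic/effector, exhausted) are
standard published marker panels and are usable as-is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

TUMOR_FEATURE = "tumor-feature"
MICROENV_FEATURE = "microenvironment-feature"


class ConfigError(ValueError):
    """Raised for malformed signature or analysis configuration."""


@dataclass(frozen=True)
class Signature:
    """A named gene list with its feature category and class tag."""

    name: str
    genes: tuple[str, ...]
    category: str = MICROENV_FEATURE
    tag: str = ""

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ConfigError(f"signature {self.name!r} has an empty gene list")
        if self.category not in (TUMOR_FEATURE, MICROENV_FEATURE):
            raise ConfigError(f"unknown category {self.category!r}")


class SignatureSet:
    """Ordered collection of uniquely named signatures."""

    def __init__(self, signatures: Iterable[Signature]):
        self._sigs: dict[str, Signature] = {}
        for sig in signatures:
            if sig.name in self._sigs:
                raise ConfigError(f"duplicate signature name {sig.name!r}")
            self._sigs[sig.name] = sig
        if not self._sigs:
            raise ConfigError("signature set is empty")

    def __len__(self) -> int:
        return len(self._sigs)

    def __iter__(self):
        return iter(self._sigs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sigs

    def __getitem__(self, name: str) -> Signature:
        return self._sigs[name]

    @property
    def names(self) -> list[str]:
        return list(self._sigs)

    def genes(self, name: str) -> tuple[str, ...]:
        return self._sigs[name].genes

    def all_genes(self) -> set[str]:
        return {g for s in self for g in s.genes}

    def priority_order(self) -> list[str]:
        """Deterministic tie-break order: tumor features first, then
        microenvironment features, lexicographic within each group."""
        tumor = sorted(n for n, s in self._sigs.items() if s.category == TUMOR_FEATURE)
        micro = sorted(n for n, s in self._sigs.items() if s.category == MICROENV_FEATURE)
        return tumor + micro

    def to_dict(self) -> dict:
        return {
            s.name: {"genes": list(s.genes), "category": s.category, "tag": s.tag}
            for s in self
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SignatureSet":
        sigs = []
        for name, spec in d.items():
            if isinstance(spec, (list, tuple)):
                sigs.append(Signature(name, tuple(spec)))
            else:
                sigs.append(
                    Signature(
                        name,
                        tuple(spec["genes"]),
                        spec.get("category", MICROENV_FEATURE),
                        spec.get("tag", name),
                    )
                )
        return cls(sigs)


# Feature classes used throughout the pipeline; enclave planting and
# "possibly malignant" region calling target the proliferative/invasive pair.
DEFAULT_FEATURE_CLASSES: tuple[tuple[str, str], ...] = (
    ("well-differentiated", TUMOR_FEATURE),
    ("proliferative", TUMOR_FEATURE),
    ("invasive", TUMOR_FEATURE),
    ("B cell", MICROENV_FEATURE),
    ("T cell", MICROENV_FEATURE),
    ("fibroblast-CAF", MICROENV_FEATURE),
    ("macrophage", MICROENV_FEATURE),
)


def default_signatures(n_genes: int = 20) -> SignatureSet:
    """Synthetic stand-in signature set covering the default feature classes.

    Gene names are generated (``INVASIVE_001`` ...) and match the genes the
    synthetic section generator plants, so the packaged defaults and the
    simulator agree.  Replace with curated lists for real data.
    """
    sigs = []
    for name, category in DEFAULT_FEATURE_CLASSES:
        stem = name.upper().replace(" ", "_").replace("-", "_")
        genes = tuple(f"{stem}_{i:03d}" for i in range(1, n_genes + 1))
        sigs.append(Signature(name, genes, category, tag=name))
    return SignatureSet(sigs)


def tcell_state_sets() -> dict[str, tuple[str, ...]]:
    """Published T-cell state marker panels for module scoring."""
    return {
        "naive T": ("TCF7", "LEF1", "CCR7", "SELL", "MALL"),
        "cytotoxic/effector T": (
            "CST7", "GZMK", "GZMA", "NKG7", "IFNG", "PRF1", "GZMB", "GNLY",
        ),
        "exhausted T": (
            "PDCD1", "TOX", "CXCL13", "TIGIT", "CTLA4", "TNFRSF9", "HAVCR2", "LAG3",
        ),
    }


@dataclass
class AnalysisConfig:
    """Tunable constants of the pipeline.

    ``frac_of_max``, ``floor`` and ``min_region_spots`` implement the
    possibly-malignant threshold rule (threshold = 70% of the section
    maximum local enrichment score, floored at 10; regions must exceed 15
    spots).  ``min_score`` is the z-like PAGE floor below which a spot is
    left unassigned.  ``slope_threshold`` is per unit normalized trajectory
    length.  ``corridor_width`` is in spot-pitch units.
    """

    min_score: float = 2.0
    slope_threshold: float = 0.02
    slope_thresholds: dict = field(default_factory=dict)  # per-signature overrides
    corridor_width: float = 2.0  # × spot pitch
    kernel_radius: int = 6
    ring_weights: tuple[float, ...] = (12.0, 11.0, 10.0, 9.0, 8.0, 7.0, 6.0)
    frac_of_max: float = 0.7
    floor: float = 10.0
    min_region_spots: int = 15
    n_bins: int = 100
    smooth_window: int = 11
    fdr_level: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.frac_of_max <= 1):
            raise ConfigError("frac_of_max must lie in (0, 1]")
        if self.floor < 0:
            raise ConfigError("floor must be non-negative")
        if self.min_region_spots < 1:
            raise ConfigError("min_region_spots must be >= 1")
        if len(self.ring_weights) != self.kernel_radius + 1:
            raise ConfigError("ring_weights must have length kernel_radius + 1")
        w = list(self.ring_weights)
        if any(b > a for a, b in zip(w, w[1:])):
            raise ConfigError("ring_weights must be non-increasing with ring")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be a positive odd integer")

    def slope_threshold_for(self, signature: str) -> float:
        return float(self.slope_thresholds.get(signature, self.slope_threshold))

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["ring_weights"] = list(d["ring_weights"])
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        d = json.loads(Path(path).read_text())
        if "ring_weights" in d:
            d["ring_weights"] = tuple(d["ring_weights"])
        return cls(**d)
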