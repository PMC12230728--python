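"""YAML catalogs: PAM types and genome registries.

Both catalogs are user-editable YAML so new nucleases or assemblies can
be added without code changes.  A default PAM catalog covering the
common SpCas9 (NGG/NAG/NRG), SaCas9, NmCas9 and Cas12a (TTTN/TTTV)
motifs ships with the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .search import ORIENTATIONS, PamSpec

logger = logging.getLogger(__name__)


@dataclass
class PamCatalog:
    entries: dict[str, PamSpec] = field(default_factory=dict)

    def __getitem__(self, name: str) -> PamSpec:
        try:
            return self.entries[name]
        except KeyError:
            raise KeyError(
                f"unknown PAM {name!r}; catalog has: {', '.join(sorted(self.entries))}"
            ) from None

    def names(self) -> list[str]:
        return sorted(self.entries)


@dataclass
class GenomeCatalog:
    """Species label -> reference FASTA path (+ optional description)."""

    entries: dict[str, dict] = field(default_factory=dict)

    def path(self, label: str) -> Path:
        return Path(self.entries[label]["path"])


def load_pam_yaml(path: str | Path | None = None) -> PamCatalog:
    """Load a PAM catalog; with no path, the packaged defaults.

    Entries must be a YAML list of ``{name, pattern, orientation}``;
    duplicate names, invalid IUPAC patterns and unknown orientations are
    rejected naming the offending entry.
    """
    if path is None:
        text = resources.files("allelescan.data").joinpath("pams.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, list):
        raise ValueError("PAM catalog must be a YAML list of entries")
    catalog = PamCatalog()
    for entry in raw:
        try:
            name = entry["name"]
        except (TypeError, KeyError):
            raise ValueError(f"PAM catalog entry missing 'name': {entry!r}") from None
        if name in catalog.entries:
            raise ValueError(f"duplicate PAM name {name!r} in catalog")
        orientation = entry.get("orientation", "")
        if orientation not in ORIENTATIONS:
            raise ValueError(
                f"PAM {name!r}: unknown orientation {orientation!r} "
                f"(expected one of {ORIENTATIONS})"
            )
        try:
            catalog.entries[name] = PamSpec(name, entry["pattern"], orientation)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"PAM {name!r}: {exc}") from None
    return catalog


def load_genome_yaml(path: str | Path) -> GenomeCatalog:
    """Load a genome catalog; missing FASTA paths warn per entry."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise ValueError("genome catalog must be a YAML list of entries")
    catalog = GenomeCatalog()
    for entry in raw:
        label = entry["name"]
        if label in catalog.entries:
            raise ValueError(f"duplicate genome label {label!r}")
        fasta = Path(entry["path"])
        if not fasta.exists():
            logger.warning("genome %r: FASTA %s does not exist", label, fasta)
        catalog.entries[label] = {
            "path": str(fasta),
            "description": entry.get("description", ""),
        }
    return catalog
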