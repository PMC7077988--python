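"""Bundled default motifs and library-design configuration.

The packaged PFMs and 20-bp building blocks are synthetic stand-ins built
from the field-standard consensus sites for OCT4, SOX2, KLF4 and ESRRB
(files named ``synthetic_*.jaspar``); every operation accepts user-supplied
replacements through the same loaders.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .library_design import BuildingBlock, Scaffold
from .motifs import MotifModel, load_pfm

_DATA = resources.files("cisgrammar") / "data"


def load_library_config(path: str | Path | None = None) -> dict:
    """Parse a library-design config (YAML) into typed objects.

    Returns a dict with keys ``motifs`` (TF -> MotifModel), ``blocks``
    (TF -> BuildingBlock), ``scaffolds`` (name -> Scaffold) and
    ``restriction_sites`` (enzyme -> site).  With ``path=None`` the bundled
    synthetic defaults are used.
    """
    if path is None:
        text = (_DATA / "default_library.yaml").read_text()
        motif_dir: Path | None = None
    else:
        text = Path(path).read_text()
        motif_dir = Path(path).parent
    raw = yaml.safe_load(text)

    motifs: dict[str, MotifModel] = {}
    for tf, fname in raw.get("motifs", {}).items():
        if motif_dir is None:
            with resources.as_file(_DATA / fname) as p:
                motifs[tf] = load_pfm(p, "jaspar")
        else:
            motifs[tf] = load_pfm(motif_dir / fname, "jaspar")
        motifs[tf].name = tf

    blocks = {
        tf: BuildingBlock(tf, spec["sequence"], spec["site_start"], spec["site_length"])
        for tf, spec in raw.get("blocks", {}).items()
    }
    scaffolds = {
        name: Scaffold(spec["template"], spec["total_length"])
        for name, spec in raw.get("scaffolds", {}).items()
    }
    return {
        "motifs": motifs,
        "blocks": blocks,
        "scaffolds": scaffolds,
        "restriction_sites": dict(raw.get("restriction_sites", {})),
        "barcode": dict(raw.get("barcode", {})),
    }


def default_motifs() -> dict[str, MotifModel]:
    """The four bundled synthetic pluripotency-factor motifs (O, S, K, E)."""
    return load_library_config()["motifs"]


def default_blocks() -> dict[str, BuildingBlock]:
    """The bundled synthetic 20-bp building blocks."""
    return load_library_config()["blocks"]
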