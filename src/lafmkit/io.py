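"""File formats, stack codes, and configuration plumbing.

Stacks travel as multi-page float32 TIFF (heights in Å) with a JSON
sidecar carrying the stack code and acquisition metadata.  Atomic
structures are read from standard PDB files (single- or multi-model) with
van der Waals radii assigned from a bundled element table.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .simafm import AtomSet, ImageStack

__all__ = [
    "StackCode",
    "parse_stack_code",
    "VDW_RADII",
    "read_pdb_atoms",
    "write_frames_pdb",
    "write_stack",
    "read_stack",
    "save_recipe",
    "load_recipe",
]

_EN_DASH = "–"


@dataclass(frozen=True)
class StackCode:
    """Stack provenance code, e.g. "AC–20–2".

    alignment A (aligned) or U (unaligned); side C (cytoplasmic) or P
    (periplasmic); tip radius and pixel size in Å.  Formats with the en
    dash exactly as conventionally printed.
    """

    alignment: str
    side: str
    tip_radius: int
    pixel_size: int

    def __post_init__(self) -> None:
        if self.alignment not in ("A", "U"):
            raise ValueError(f"invalid alignment flag {self.alignment!r} (expected A or U)")
        if self.side not in ("C", "P"):
            raise ValueError(f"invalid membrane side {self.side!r} (expected C or P)")
        if self.tip_radius <= 0:
            raise ValueError("tip radius must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    def __str__(self) -> str:
        return f"{self.alignment}{self.side}{_EN_DASH}{self.tip_radius}{_EN_DASH}{self.pixel_size}"


_CODE_RE = re.compile(rf"^([A-Z])([A-Z])[{_EN_DASH}-](\d+)[{_EN_DASH}-](\d+)$")


def parse_stack_code(text: str) -> StackCode:
    """Parse a stack code such as "AC–20–2" (en dash or ASCII hyphen)."""
    m = _CODE_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed stack code {text!r}: expected [AU][CP]–<tip>–<pixel>")
    return StackCode(m.group(1), m.group(2), int(m.group(3)), int(m.group(4)))


# CHARMM-like van der Waals radii (Å) by element; a per-atom radius column
# in the input overrides the table.
VDW_RADII = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 1.80,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 1.80,
    "NA": 2.27,
    "K": 2.75,
}
_DEFAULT_RADIUS = 1.70


def _membrane_background(positions: np.ndarray, elements: np.ndarray) -> float:
    """Membrane plane: mean z of upper-leaflet phosphorus atoms, else 0."""
    p = positions[elements == "P"]
    if p.shape[0] == 0:
        return 0.0
    upper = p[:, 2] >= np.median(p[:, 2])
    return float(p[upper, 2].mean())


def read_pdb_atoms(
    path,
    radius_table: "dict[str, float] | None" = None,
    radius_overrides: "np.ndarray | None" = None,
) -> list[AtomSet]:
    """Read a single- or multi-model PDB file into per-frame atom sets.

    Radii come from the element table unless ``radius_overrides`` (one
    radius per atom) is given.  If phosphorus atoms are present the
    membrane background is set to the mean z of the upper leaflet,
    otherwise to 0.
    """
    import warnings

    from biotite.structure.io.pdb import PDBFile

    table = dict(VDW_RADII if radius_table is None else radius_table)
    # light pre-validation so coordinate errors carry a line number
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                n_atoms += 1
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: malformed coordinate field at line {lineno}"
                    ) from exc
    if n_atoms == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure()  # AtomArrayStack (models x atoms)
    if arr.array_length() == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    elements = np.char.upper(arr.element.astype(str))
    if radius_overrides is not None:
        radii = np.asarray(radius_overrides, dtype=float)
        if radii.shape[0] != arr.array_length():
            raise ValueError("radius_overrides length does not match atom count")
    else:
        unknown = sorted(set(elements) - set(table))
        if unknown:
            warnings.warn(f"unknown elements {unknown}: using default radius "
                          f"{_DEFAULT_RADIUS} Å")
        radii = np.array([table.get(e, _DEFAULT_RADIUS) for e in elements])
    frames = []
    for model in range(arr.stack_depth()):
        coords = np.asarray(arr.coord[model], dtype=float)
        bg = _membrane_background(coords, elements)
        frames.append(AtomSet(coords, radii.copy(), bg))
    return frames


def write_frames_pdb(path, frames: list[AtomSet]) -> None:
    """Write per-frame atom sets as a multi-model PDB (pseudo-carbon atoms)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if not frames:
        raise ValueError("no frames to write")
    n = len(frames[0])
    coords = np.stack([np.asarray(f.positions, dtype=np.float32) for f in frames])
    if any(len(f) != n for f in frames):
        raise ValueError("all frames must have the same atom count")
    arr = struc.AtomArrayStack(len(frames), n)
    arr.coord = coords
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.full(n, "UNK")
    arr.atom_name = np.full(n, "C")
    arr.element = np.full(n, "C")
    arr.hetero = np.full(n, True)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def save_recipe(path, recipe) -> None:
    """Serialize a StackRecipe to YAML."""
    import yaml

    payload = {
        "n_frames": recipe.n_frames,
        "state_sequence_mode": recipe.state_sequence_mode,
        "seed": recipe.seed,
        "markov_stay_prob": recipe.markov_stay_prob,
        "background_z": recipe.background_z,
        "motion": {
            "jitter_sigma": recipe.motion.jitter_sigma,
            "drift_translation_sigma": recipe.motion.drift_translation_sigma,
            "drift_rotation_sigma": recipe.motion.drift_rotation_sigma,
            "aligned": recipe.motion.aligned,
        },
        "conformers": [
            {
                "conformer_id": c.conformer_id,
                "occupancy": c.occupancy,
                "domains": [
                    {"center": list(d.center), "n_atoms": d.n_atoms,
                     "spread": d.spread, "atom_radius": d.atom_radius}
                    for d in c.domains
                ],
            }
            for c in recipe.conformers
        ],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_recipe(path):
    """Load a StackRecipe from YAML; unknown keys are rejected."""
    import yaml

    from .synth import ConformerSpec, Domain, MotionModel, StackRecipe

    data = yaml.safe_load(Path(path).read_text())
    known = {"n_frames", "state_sequence_mode", "seed", "markov_stay_prob",
             "background_z", "motion", "conformers"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown recipe keys: {sorted(unknown)}")
    motion = MotionModel(**data["motion"])
    conformers = tuple(
        ConformerSpec(
            conformer_id=c["conformer_id"],
            occupancy=c["occupancy"],
            domains=tuple(
                Domain(tuple(d["center"]), d["n_atoms"], d["spread"], d["atom_radius"])
                for d in c["domains"]
            ),
        )
        for c in data["conformers"]
    )
    return StackRecipe(
        conformers=conformers,
        motion=motion,
        n_frames=data["n_frames"],
        state_sequence_mode=data.get("state_sequence_mode", "block"),
        seed=data.get("seed", 0),
        markov_stay_prob=data.get("markov_stay_prob", 0.97),
        background_z=data.get("background_z", 0.0),
    )


def write_stack(path, stack: ImageStack, extra_meta: "dict | None" = None) -> None:
    """Write a stack as multi-page float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    if not np.isfinite(stack.heights).all():
        raise ValueError("stack contains non-finite values")
    tifffile.imwrite(path, stack.heights.astype(np.float32))
    sidecar = {
        "code": str(stack.code) if stack.code is not None else None,
        "pixel_size_A": stack.pixel_size,
    }
    sidecar.update(stack.meta)
    if extra_meta:
        sidecar.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path) -> ImageStack:
    """Read a TIFF stack and its JSON sidecar (defaults if absent, with warning)."""
    import warnings

    path = Path(path)
    heights = tifffile.imread(path)
    if heights.ndim == 2:
        heights = heights[None]
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    else:
        warnings.warn(f"missing sidecar for {path}; assuming pixel size 1 Å/px")
        meta = {}
    code = parse_stack_code(meta["code"]) if meta.get("code") else None
    pixel_size = float(meta.get("pixel_size_A", 1.0))
    stack = ImageStack(heights.astype(np.float32), pixel_size, code=code)
    stack.meta = {k: v for k, v in meta.items() if k not in ("code", "pixel_size_A")}
    return stack
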