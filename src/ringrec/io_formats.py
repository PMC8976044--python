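"""Domain types and file IO for particle metadata, density volumes and models.

Formats:

* particle tables — STAR dialect (``loop_`` with named tags, RELION-style
  tag names); unknown tags are carried through verbatim and never
  interpreted.
* volumes / image stacks — MRC2014, mode 2 (32-bit float) only.
* atomic models — PDB / mmCIF via biotite; entity descriptions are taken
  from the mmCIF ``entity`` category when present.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .geometry import TransformRT, normalize_angle

__all__ = [
    "ParticleRecord",
    "ParticleTable",
    "VolumeGrid",
    "ImageStack",
    "Residue",
    "Chain",
    "SSEAnnotation",
    "AtomicModel",
    "SchemaError",
    "read_particle_table",
    "write_particle_table",
    "read_volume",
    "write_volume",
    "read_image_stack",
    "write_image_stack",
    "read_model",
    "write_model",
    "read_sse_table",
    "write_sse_table",
    "binned_pixel_size",
]


class SchemaError(ValueError):
    """Raised when a particle table misses a mandatory column."""


def binned_pixel_size(base_pixel_size: float, binning: float) -> float:
    """Physical pixel size after Fourier-cropping / binning by ``binning``.

    E.g. a 0.6935 A super-resolution pixel binned twice gives 1.387 A, and a
    further factor two (bin-2 extraction) gives 2.774 A.
    """
    if base_pixel_size <= 0 or binning <= 0:
        raise ValueError("pixel size and binning must be positive")
    return base_pixel_size * binning


# ---------------------------------------------------------------------------
# particle tables
# ---------------------------------------------------------------------------

#: canonical column name -> STAR tag
_STAR_TAGS = {
    "image_name": "_rlnImageName",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
    "shift_x": "_rlnOriginXAngst",
    "shift_y": "_rlnOriginYAngst",
    "defocus_u": "_rlnDefocusU",
    "defocus_v": "_rlnDefocusV",
    "astig_angle": "_rlnDefocusAngle",
    "pixel_size": "_rlnImagePixelSize",
    "group_id": "_rlnGroupNumber",
    "subunit_index": "_rlnSubunitIndex",
}
_TAG_TO_COLUMN = {tag: col for col, tag in _STAR_TAGS.items()}

_MANDATORY = (
    "rot",
    "tilt",
    "psi",
    "shift_x",
    "shift_y",
    "defocus_u",
    "defocus_v",
)

_INT_COLUMNS = ("group_id", "subunit_index")


@dataclass
class ParticleRecord:
    """Per-particle pose, shift and CTF parameters.

    ``(rot, tilt, psi)`` are intrinsic ZYZ Euler angles (degrees) mapping the
    reference frame to the particle projection frame; ``shift_x/y`` translate
    the projected reference within the image (Angstrom); defoci in Angstrom.
    """

    image_name: str = ""
    image_index: int = 0
    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    shift_x: float = 0.0
    shift_y: float = 0.0
    defocus_u: float = 20000.0
    defocus_v: float = 20000.0
    astig_angle: float = 0.0
    pixel_size: float = 1.0
    group_id: int = 0
    subunit_index: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rot = normalize_angle(self.rot)
        self.psi = normalize_angle(self.psi)
        if not 0.0 <= self.tilt <= 180.0:
            raise ValueError(f"tilt must lie in [0, 180], got {self.tilt}")
        if self.defocus_u <= 0 or self.defocus_v <= 0:
            raise ValueError("defocus must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


class ParticleTable:
    """Ordered particle metadata with a closed, named-column schema.

    Backed by a :class:`pandas.DataFrame` using the canonical column names of
    :class:`ParticleRecord`; any other columns are opaque extras preserved on
    round trip.  All records share one pixel size.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "") -> None:
        missing = [c for c in _MANDATORY if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        if "pixel_size" not in df.columns:
            raise SchemaError("missing mandatory column(s): pixel_size")
        df = df.reset_index(drop=True).copy()
        df["rot"] = [normalize_angle(a) for a in df["rot"]]
        df["psi"] = [normalize_angle(a) for a in df["psi"]]
        if ((df["tilt"] < 0) | (df["tilt"] > 180)).any():
            raise ValueError("tilt must lie in [0, 180]")
        if len(df) and df["pixel_size"].nunique() != 1:
            raise ValueError("all records must share one pixel_size")
        self.df = df
        self.provenance = provenance

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[ParticleRecord], provenance: str = ""
    ) -> "ParticleTable":
        rows = []
        for rec in records:
            row = {
                k: getattr(rec, k)
                for k in list(_STAR_TAGS) + ["image_index"]
                if getattr(rec, k) is not None
            }
            row.update(rec.extras)
            rows.append(row)
        if not rows:
            raise ValueError("cannot build a table from zero records")
        return cls(pd.DataFrame(rows), provenance=provenance)

    # -- container protocol --------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[ParticleRecord]:
        return iter(self.records())

    def records(self) -> list[ParticleRecord]:
        known = [
            c
            for c in list(_STAR_TAGS) + ["image_index"]
            if c in self.df.columns
        ]
        extras_cols = [
            c for c in self.df.columns if c not in _STAR_TAGS and c != "image_index"
        ]
        out = []
        for d in self.df.to_dict("records"):
            kwargs = {k: d[k] for k in known}
            if "subunit_index" in kwargs and pd.isna(kwargs["subunit_index"]):
                kwargs["subunit_index"] = None
            out.append(
                ParticleRecord(**kwargs, extras={c: d[c] for c in extras_cols})
            )
        return out

    @property
    def pixel_size(self) -> float:
        return float(self.df["pixel_size"].iloc[0])

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()

    def with_rows(self, df: pd.DataFrame, provenance: str | None = None) -> "ParticleTable":
        return ParticleTable(
            df, provenance=self.provenance if provenance is None else provenance
        )

    def copy(self) -> "ParticleTable":
        return ParticleTable(self.df.copy(), provenance=self.provenance)


def _format_star_value(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return "1" if value else "0"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return f"{float(value):.6f}"
    return str(value)


def write_particle_table(table: ParticleTable, path: str | Path) -> None:
    """Write a loop-structured STAR-dialect particle table."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty particle table")
    df = table.df
    columns = [c for c in _STAR_TAGS if c in df.columns and c != "image_index"]
    extra_cols = [c for c in df.columns if c not in _STAR_TAGS and c != "image_index"]
    tags = [_STAR_TAGS[c] for c in columns] + extra_cols

    lines = ["", "data_particles", ""]
    if table.provenance:
        lines.insert(0, f"# {table.provenance}")
    lines.append("loop_")
    for i, tag in enumerate(tags, start=1):
        lines.append(f"{tag} #{i}")

    has_index = "image_index" in df.columns
    formatted: list[list[str]] = []
    for col in columns:
        if col == "image_name":
            indices = (
                df["image_index"].astype(int) + 1
                if has_index
                else pd.Series([1] * len(df))
            )
            formatted.append(
                [f"{i:06d}@{n}" for i, n in zip(indices, df["image_name"])]
            )
        elif col == "subunit_index":
            formatted.append(
                ["-1" if pd.isna(v) else str(int(v)) for v in df[col]]
            )
        else:
            formatted.append([_format_star_value(v) for v in df[col]])
    for c in extra_cols:
        formatted.append([_format_star_value(v) for v in df[c]])
    for cells in zip(*formatted):
        lines.append(" ".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def _coerce_star_column(name: str, values: list[str]):
    if name == "image_name":
        return values
    if name in _INT_COLUMNS:
        return [int(float(v)) for v in values]
    if name not in _STAR_TAGS:
        return values  # unknown columns stay verbatim strings
    return [float(v) for v in values]


def read_particle_table(
    path: str | Path, pixel_size: float | None = None
) -> ParticleTable:
    """Read a loop-structured STAR-dialect particle table.

    ``pixel_size`` overrides / supplies the pixel size when the table lacks
    the pixel-size tag.
    """
    text = Path(path).read_text()
    provenance = ""
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    reading_rows = False
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("#"):
            if not provenance and not tags:
                provenance = line.lstrip("# ").strip()
            continue
        if not line:
            if reading_rows:
                break
            continue
        if line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop = True
            continue
        if in_loop and line.startswith("_"):
            tags.append(line.split()[0])
            continue
        if in_loop and tags:
            reading_rows = True
            cells = line.split()
            if len(cells) != len(tags):
                raise SchemaError(
                    f"row has {len(cells)} values for {len(tags)} tags: {line!r}"
                )
            rows.append(cells)
    if not tags or not rows:
        raise SchemaError(f"no loop-structured data found in {path}")

    columns: dict[str, list] = {}
    for j, tag in enumerate(tags):
        col = _TAG_TO_COLUMN.get(tag, tag)
        columns[col] = _coerce_star_column(col, [r[j] for r in rows])

    if "image_name" in columns:
        names, indices = [], []
        for v in columns["image_name"]:
            if "@" in v:
                idx, name = v.split("@", 1)
                names.append(name)
                indices.append(int(idx) - 1)
            else:
                names.append(v)
                indices.append(0)
        columns["image_name"] = names
        columns["image_index"] = indices

    missing = [c for c in _MANDATORY if c not in columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if "pixel_size" not in columns:
        if pixel_size is None:
            raise SchemaError(
                "missing mandatory column(s): pixel_size "
                "(supply pixel_size= to override)"
            )
        columns["pixel_size"] = [float(pixel_size)] * len(rows)
    if "subunit_index" in columns:
        columns["subunit_index"] = [
            None if v < 0 else v for v in columns["subunit_index"]
        ]
    return ParticleTable(pd.DataFrame(columns), provenance=provenance)


# ---------------------------------------------------------------------------
# volumes and stacks (MRC2014, mode 2)
# ---------------------------------------------------------------------------


@dataclass
class VolumeGrid:
    """Cubic voxel density with a physical pixel size.

    Array is indexed ``[z, y, x]``; the physical origin sits at voxel index
    ``N // 2`` on each axis (center-of-grid convention).
    """

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"volume must be cubic, got shape {self.data.shape}")
        if self.data.shape[0] % 2 != 0:
            raise ValueError("volume side length must be even")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def physical_z(self) -> np.ndarray:
        """Physical z coordinate (A) of each z-plane."""
        n = self.n
        return (np.arange(n) - n // 2) * self.pixel_size


@dataclass
class ImageStack:
    """Stack of square particle images sharing one pixel size."""

    data: np.ndarray
    pixel_size: float
    name: str = "stack.mrcs"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise ValueError(f"stack must be (n, N, N), got {self.data.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_images(self) -> int:
        return self.data.shape[0]

    @property
    def box(self) -> int:
        return self.data.shape[1]


_MRC_HEADER_SIZE = 1024
_MRC_MODE_FLOAT32 = 2


def _write_mrc(data: np.ndarray, pixel_size: float, path: str | Path, ispg: int) -> None:
    data = np.ascontiguousarray(data, dtype="<f4")
    nz, ny, nx = data.shape
    header = bytearray(_MRC_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, _MRC_MODE_FLOAT32)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, ispg)
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 1)
    header[224:224 + 80] = b"ringrec".ljust(80)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def _read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    raw = Path(path).read_bytes()
    if len(raw) < _MRC_HEADER_SIZE:
        raise ValueError(f"{path}: truncated MRC header")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    mode = struct.unpack_from("<i", raw, 12)[0]
    if mode != _MRC_MODE_FLOAT32:
        raise ValueError(f"{path}: only MRC mode 2 (float32) supported, got {mode}")
    mx = struct.unpack_from("<i", raw, 28)[0]
    xlen = struct.unpack_from("<f", raw, 40)[0]
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    pixel = xlen / mx if mx > 0 else 0.0
    offset = _MRC_HEADER_SIZE + nsymbt
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype="<f4", count=count, offset=offset)
    return data.reshape(nz, ny, nx).copy(), pixel


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    _write_mrc(volume.data, volume.pixel_size, path, ispg=1)


def read_volume(path: str | Path, pixel_size: float | None = None) -> VolumeGrid:
    data, pixel = _read_mrc(path)
    if len(set(data.shape)) != 1:
        raise ValueError(f"{path}: volume is not cubic: {data.shape}")
    if pixel <= 0:
        if pixel_size is None:
            raise ValueError(
                f"{path}: header has no pixel size; supply pixel_size= to override"
            )
        pixel = pixel_size
    return VolumeGrid(data=data, pixel_size=pixel)


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    _write_mrc(stack.data, stack.pixel_size, path, ispg=0)


def read_image_stack(path: str | Path, pixel_size: float | None = None) -> ImageStack:
    data, pixel = _read_mrc(path)
    if pixel <= 0:
        if pixel_size is None:
            raise ValueError(
                f"{path}: header has no pixel size; supply pixel_size= to override"
            )
        pixel = pixel_size
    return ImageStack(data=data, pixel_size=pixel, name=Path(path).name)


# ---------------------------------------------------------------------------
# atomic models
# ---------------------------------------------------------------------------


@dataclass
class Residue:
    number: int
    aa: str
    ca: np.ndarray
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if "CA" not in self.atoms:
            self.atoms["CA"] = self.ca


@dataclass
class Chain:
    chain_id: str
    entity_name: str
    residues: list[Residue]
    copy_label: str | None = None

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(
                f"chain {self.chain_id}: residue numbers must strictly increase"
            )

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float).reshape(-1, 3)

    def residue(self, number: int) -> Residue:
        for res in self.residues:
            if res.number == number:
                return res
        raise KeyError(f"chain {self.chain_id} has no residue {number}")


@dataclass(frozen=True)
class SSEAnnotation:
    """Secondary-structure element annotation over a residue range."""

    label: str
    chain_id: str
    start: int
    end: int

    def covers(self, chain_id: str, number: int) -> bool:
        return chain_id == self.chain_id and self.start <= number <= self.end


@dataclass
class AtomicModel:
    """Chains of residues with Calpha (plus optional extra-atom) coordinates."""

    chains: list[Chain]
    sse: list[SSEAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError("chain ids must be unique")
        chain_map = {c.chain_id: c for c in self.chains}
        for ann in self.sse:
            chain = chain_map.get(ann.chain_id)
            if chain is None:
                raise ValueError(f"SSE {ann.label}: unknown chain {ann.chain_id}")
            numbers = {r.number for r in chain.residues}
            if ann.start not in numbers or ann.end not in numbers:
                raise ValueError(
                    f"SSE {ann.label}: range {ann.start}-{ann.end} not inside "
                    f"chain {ann.chain_id}"
                )

    def chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise KeyError(f"no chain {chain_id}")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def entity_names(self) -> list[str]:
        return sorted({c.entity_name for c in self.chains})

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def ca_coords(self) -> np.ndarray:
        parts = [c.ca_coords() for c in self.chains]
        return np.concatenate(parts) if parts else np.zeros((0, 3))

    def sse_label_for(self, chain_id: str, number: int) -> str | None:
        for ann in self.sse:
            if ann.covers(chain_id, number):
                return ann.label
        return None

    def transformed(self, rt: TransformRT, chain_suffix: str = "") -> "AtomicModel":
        chains = []
        for chain in self.chains:
            residues = [
                Residue(
                    number=r.number,
                    aa=r.aa,
                    ca=rt.apply(r.ca),
                    atoms={k: rt.apply(v) for k, v in r.atoms.items()},
                )
                for r in chain.residues
            ]
            chains.append(
                Chain(
                    chain_id=chain.chain_id + chain_suffix,
                    entity_name=chain.entity_name,
                    residues=residues,
                    copy_label=chain.copy_label,
                )
            )
        sse = [
            SSEAnnotation(a.label, a.chain_id + chain_suffix, a.start, a.end)
            for a in self.sse
        ]
        return AtomicModel(chains=chains, sse=sse)


_COPY_INFO_CATEGORY = "ringrec_chain_info"


def write_model(model: AtomicModel, path: str | Path) -> None:
    """Write a model as mmCIF (all atoms, entity descriptions preserved)."""
    import biotite.structure as struc
    import biotite.structure.io.pdbx as pdbx

    n_atoms = sum(len(r.atoms) for c in model.chains for r in c.residues)
    atoms = struc.AtomArray(n_atoms)
    entity_names = list(dict.fromkeys(c.entity_name for c in model.chains))
    entity_ids = {name: str(i + 1) for i, name in enumerate(entity_names)}
    label_entity = np.empty(n_atoms, dtype="U8")
    i = 0
    for chain in model.chains:
        for res in chain.residues:
            for atom_name, coord in res.atoms.items():
                atoms.coord[i] = coord
                atoms.chain_id[i] = chain.chain_id
                atoms.res_id[i] = res.number
                atoms.res_name[i] = res.aa
                atoms.atom_name[i] = atom_name
                atoms.element[i] = "C" if atom_name.startswith("C") else atom_name[0]
                atoms.hetero[i] = False
                label_entity[i] = entity_ids[chain.entity_name]
                i += 1

    cif = pdbx.CIFFile()
    pdbx.set_structure(cif, atoms, data_block="model")
    block = cif.block
    block["entity"] = pdbx.CIFCategory(
        {
            "id": list(entity_ids.values()),
            "pdbx_description": entity_names,
            "type": ["polymer"] * len(entity_names),
        }
    )
    atom_site = block["atom_site"]
    atom_site["label_entity_id"] = label_entity
    block[_COPY_INFO_CATEGORY] = pdbx.CIFCategory(
        {
            "chain_id": [c.chain_id for c in model.chains],
            "entity_name": [c.entity_name for c in model.chains],
            "copy_label": [c.copy_label or "." for c in model.chains],
        }
    )
    cif.write(str(path))


def _entity_descriptions(block) -> dict[str, str]:
    try:
        entity = block["entity"]
        ids = entity["id"].as_array(str)
        descs = entity["pdbx_description"].as_array(str)
        return dict(zip(ids, descs))
    except KeyError:
        return {}


def read_model(
    path: str | Path,
    entity_map: dict[str, str] | None = None,
    copy_labels: dict[str, str] | None = None,
) -> AtomicModel:
    """Read a PDB or mmCIF model into chains of residues with Calpha coords.

    ``entity_map`` maps chain id -> entity name and overrides (or supplies,
    for PDB input) entity descriptions.  ``copy_labels`` maps chain id ->
    copy label (e.g. ``"inner"`` / ``"outer"``).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    copy_labels = dict(copy_labels or {})
    chain_entity: dict[str, str] = dict(entity_map or {})

    if suffix in (".cif", ".mmcif", ".pdbx"):
        import biotite.structure.io.pdbx as pdbx

        cif = pdbx.CIFFile.read(str(path))
        block = cif.block
        atoms = pdbx.get_structure(
            cif, model=1, extra_fields=["label_entity_id"]
        )
        if not entity_map:
            desc = _entity_descriptions(block)
            for cid, eid in zip(atoms.chain_id, atoms.label_entity_id):
                chain_entity.setdefault(str(cid), desc.get(str(eid), str(cid)))
        if _COPY_INFO_CATEGORY in block:
            info = block[_COPY_INFO_CATEGORY]
            ids = np.atleast_1d(info["chain_id"].as_array(str))
            ents = np.atleast_1d(info["entity_name"].as_array(str))
            labels = np.atleast_1d(info["copy_label"].as_array(str))
            for cid, ent, lab in zip(ids, ents, labels):
                if not entity_map:
                    chain_entity[str(cid)] = str(ent)
                if str(lab) != "." and str(cid) not in copy_labels:
                    copy_labels[str(cid)] = str(lab)
    elif suffix in (".pdb", ".ent"):
        import biotite.structure.io.pdb as pdbio

        atoms = pdbio.PDBFile.read(str(path)).get_structure(model=1)
    else:
        raise ValueError(f"unrecognized model format: {path}")

    atoms = atoms[~atoms.hetero]
    chains: list[Chain] = []
    for cid in list(dict.fromkeys(atoms.chain_id)):
        sel = atoms[atoms.chain_id == cid]
        residues: list[Residue] = []
        for number in list(dict.fromkeys(sel.res_id)):
            rsel = sel[sel.res_id == number]
            names = list(rsel.atom_name)
            if "CA" not in names:
                continue
            coords = {n: rsel.coord[i] for i, n in enumerate(names)}
            residues.append(
                Residue(
                    number=int(number),
                    aa=str(rsel.res_name[0]),
                    ca=coords["CA"],
                    atoms=coords,
                )
            )
        if not residues:
            warnings.warn(f"chain {cid}: no Calpha atoms, skipped")
            continue
        chains.append(
            Chain(
                chain_id=str(cid),
                entity_name=chain_entity.get(str(cid), str(cid)),
                residues=residues,
                copy_label=copy_labels.get(str(cid)),
            )
        )
    if not chains:
        raise ValueError(f"{path}: no polymer chain with Calpha atoms")
    return AtomicModel(chains=chains)


# ---------------------------------------------------------------------------
# SSE annotation tables
# ---------------------------------------------------------------------------


def write_sse_table(annotations: Sequence[SSEAnnotation], path: str | Path) -> None:
    lines = ["label\tchain\tstart\tend"]
    for a in annotations:
        lines.append(f"{a.label}\t{a.chain_id}\t{a.start}\t{a.end}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_sse_table(path: str | Path) -> list[SSEAnnotation]:
    lines = Path(path).read_text().strip().splitlines()
    out = []
    for line in lines[1:]:
        label, chain, start, end = line.split("\t")
        out.append(SSEAnnotation(label, chain, int(start), int(end)))
    return out
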