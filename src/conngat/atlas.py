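"""ROI atlas tables: identifiers, MNI coordinates and functional-network labels.

The default parcellation convention is a 264-node functional atlas in which
every region carries an anatomical label and a functional-network code
(DMN, VIS, FRNT, SAL, SM Hand, SM Mouth, MEM, CB, UNK, ...).  ROI ids are
1-based in all files, 0-based internally; the reader/writer is the boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Functional-network codes of the standard 264-node parcellation.
STANDARD_NETWORKS = (
    "SM Hand", "SM Mouth", "VIS", "DMN", "FRNT", "SAL", "MEM", "CB",
    "AUD", "CO", "SUB", "VAN", "DAN", "UNK",
)

DEFAULT_N_ROIS = 264


@dataclass
class RoiAtlas:
    """Table of ROIs: 1-based id, MNI mm coordinates, labels.

    Parameters
    ----------
    roi_id : (N,) int array, unique and contiguous starting at 1.
    mni_xyz : (N, 3) float array of MNI coordinates in mm.
    anatomical_label : (N,) array of region names.
    network_label : (N,) array of functional-network codes; missing values
        are mapped to ``"UNK"``.
    """

    roi_id: np.ndarray
    mni_xyz: np.ndarray
    anatomical_label: np.ndarray
    network_label: np.ndarray
    networks: tuple = field(init=False)

    def __post_init__(self):
        self.roi_id = np.asarray(self.roi_id, dtype=int)
        self.mni_xyz = np.asarray(self.mni_xyz, dtype=float)
        self.anatomical_label = np.asarray(self.anatomical_label, dtype=object)
        labels = [
            "UNK" if (l is None or (isinstance(l, float) and np.isnan(l)) or str(l).strip() == "")
            else str(l).strip()
            for l in np.asarray(self.network_label, dtype=object)
        ]
        self.network_label = np.asarray(labels, dtype=object)
        n = len(self.roi_id)
        if len(np.unique(self.roi_id)) != n:
            dupes = self.roi_id[pd.Index(self.roi_id).duplicated()]
            raise ValueError(f"duplicate roi_id values: {sorted(set(dupes))}")
        if not np.array_equal(np.sort(self.roi_id), np.arange(1, n + 1)):
            raise ValueError("roi_id must be contiguous 1..N")
        if self.mni_xyz.shape != (n, 3):
            raise ValueError(f"mni_xyz must be (N, 3), got {self.mni_xyz.shape}")
        self.networks = tuple(sorted(set(self.network_label)))

    def __len__(self) -> int:
        return len(self.roi_id)

    @property
    def n_rois(self) -> int:
        return len(self.roi_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": self.roi_id,
                "mni": [" ".join(f"{v:g}" for v in xyz) for xyz in self.mni_xyz],
                "anatomical_region": self.anatomical_label,
                "functional_network": self.network_label,
            }
        )

    def network_of(self, roi_id_1based: int) -> str:
        idx = np.flatnonzero(self.roi_id == roi_id_1based)
        if idx.size == 0:
            raise KeyError(f"ROI {roi_id_1based} not in atlas")
        return str(self.network_label[idx[0]])


def _parse_mni(cell) -> list[float]:
    parts = str(cell).replace("−", "-").split()
    if len(parts) != 3:
        raise ValueError(f"MNI coordinate cell {cell!r} must contain 3 numbers")
    return [float(p) for p in parts]


def read_atlas(path, networks: tuple | None = None) -> RoiAtlas:
    """Read an atlas from a delimited table or a JSON record list.

    Delimited files need four columns (roi id, "x y z" MNI triple, anatomical
    label, network code); delimiter is autodetected between comma and tab.
    When `networks` is given, any code outside it raises.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame.from_records(records)
    else:
        text = path.read_text()
        sep = "\t" if "\t" in text.splitlines()[0] else ","
        df = pd.read_csv(path, sep=sep, header=None if _headerless(text, sep) else 0)
        df.columns = ["roi", "mni", "anatomical_region", "functional_network"][: df.shape[1]]
    if df.shape[1] < 4:
        raise ValueError(f"atlas table must have 4 columns, found {df.shape[1]}")
    mni = np.array([_parse_mni(c) for c in df["mni"]])
    atlas = RoiAtlas(
        roi_id=df["roi"].to_numpy(),
        mni_xyz=mni,
        anatomical_label=df["anatomical_region"].to_numpy(),
        network_label=df["functional_network"].to_numpy(),
    )
    if networks is not None:
        unknown = set(atlas.network_label) - set(networks) - {"UNK"}
        if unknown:
            raise ValueError(f"unknown network code(s): {sorted(unknown)}")
    return atlas


def _headerless(text: str, sep: str) -> bool:
    first = text.splitlines()[0].split(sep)[0].strip()
    try:
        int(first)
        return True
    except ValueError:
        return False


def write_atlas(atlas: RoiAtlas, path) -> None:
    """Write the atlas as CSV (or JSON records when the path ends in .json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = atlas.to_frame().to_dict(orient="records")
        path.write_text(json.dumps(records, indent=1))
    else:
        atlas.to_frame().to_csv(path, index=False)


def synthetic_atlas(n_rois: int, network_labels) -> RoiAtlas:
    """Build a synthetic atlas with given per-ROI network labels.

    Coordinates are placed on a deterministic grid; intended for simulated
    cohorts where the network structure, not anatomy, matters.
    """
    ids = np.arange(1, n_rois + 1)
    grid = np.stack(
        [ids % 10 * 10.0 - 45.0, ids // 10 % 10 * 10.0 - 45.0, ids // 100 * 10.0],
        axis=1,
    )
    return RoiAtlas(
        roi_id=ids,
        mni_xyz=grid,
        anatomical_label=np.array([f"synthetic region {i}" for i in ids], dtype=object),
        network_label=np.asarray(network_labels, dtype=object),
    )
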