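"""Readers, writers, configuration and provenance.

Conventions
-----------
* Tables are comma-separated UTF-8 CSV with a header row and ``.``
  decimal point; coordinates are in µm; axial positions are normalized
  to [0, 1].
* Locus focus coordinates are serialized in a single ``locus_foci``
  column: coordinates within a focus are written ``x y z``
  (space-separated, µm), the 1–2 foci of one locus are separated by
  ``;`` and multiple loci by ``|``.
* Image stacks are multi-page TIFF in ZYX plane order.  The physical
  voxel size is never guessed: it must come from a plain-text sidecar
  config (``key: value`` lines with ``voxel_size_z_nm`` /
  ``voxel_size_y_nm`` / ``voxel_size_x_nm``).
* Voxel indices are 0-based ZYX; physical coordinate = (index + 0.5) ×
  voxel size.
* Every pipeline run can write a JSON provenance sidecar (package
  version, timestamp, resolved parameters, config hash) so reruns are
  reproducible at the count level.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .chiasma import CountDistribution
from .pairing import NucleusRecord

__all__ = [
    "read_nucleus_table",
    "write_nucleus_table",
    "read_count_distribution",
    "write_count_distribution",
    "read_stack",
    "write_stack",
    "read_config",
    "write_provenance",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("gonad_id", "nucleus_id", "axial_pos")
OPTIONAL_INT_COLUMNS = ("dapi_count", "cosa_count", "rad51_count")


def _parse_locus_foci(text: str) -> List[List[Tuple[float, float, float]]]:
    loci = []
    for locus_str in str(text).split("|"):
        locus_str = locus_str.strip()
        if not locus_str:
            continue
        foci = []
        for focus_str in locus_str.split(";"):
            parts = focus_str.split()
            if len(parts) != 3:
                raise ValueError(f"expected 'x y z' for a focus, got {focus_str!r}")
            x, y, z = (float(v) for v in parts)
            foci.append((z, y, x))  # stored internally as (z, y, x)
        loci.append(foci)
    return loci


def _format_locus_foci(loci) -> str:
    return "|".join(
        ";".join(f"{f[2]:.6g} {f[1]:.6g} {f[0]:.6g}" for f in locus) for locus in loci
    )


def read_nucleus_table(path) -> List[NucleusRecord]:
    """Read and validate a per-nucleus CSV into records.

    Malformed rows raise with the 1-based data row number so they can
    be located in the file.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records: List[NucleusRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            kwargs = dict(
                gonad_id=str(row["gonad_id"]),
                nucleus_id=str(row["nucleus_id"]),
                axial_pos=float(row["axial_pos"]),
            )
            if "stage" in row and not pd.isna(row["stage"]):
                kwargs["stage"] = str(row["stage"])
            for col in OPTIONAL_INT_COLUMNS:
                if col in row and not pd.isna(row[col]):
                    kwargs[col] = int(row[col])
            if "locus_foci" in row and not pd.isna(row["locus_foci"]):
                kwargs["locus_foci"] = _parse_locus_foci(row["locus_foci"])
            for col in ("k_true", "matured_true"):
                if col in row and not pd.isna(row[col]):
                    kwargs[col] = int(row[col])
            if "paired_true" in row and not pd.isna(row["paired_true"]):
                kwargs["paired_true"] = bool(row["paired_true"])
            records.append(NucleusRecord(**kwargs))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
    return records


def write_nucleus_table(records: Sequence[NucleusRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "gonad_id": r.gonad_id,
                "nucleus_id": r.nucleus_id,
                "axial_pos": r.axial_pos,
                "stage": r.stage,
                "dapi_count": r.dapi_count,
                "cosa_count": r.cosa_count,
                "rad51_count": r.rad51_count,
                "locus_foci": _format_locus_foci(r.locus_foci) if r.locus_foci else "",
                "k_true": r.k_true,
                "matured_true": r.matured_true,
                "paired_true": r.paired_true,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_count_distribution(path, k_max: int = 6) -> CountDistribution:
    """Read a count-distribution CSV with columns ``k`` and ``n_nuclei``."""
    df = pd.read_csv(path)
    for col in ("k", "n_nuclei"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return CountDistribution(
        {int(k): float(n) for k, n in zip(df["k"], df["n_nuclei"])}, k_max=k_max
    )


def write_count_distribution(dist: CountDistribution, path) -> None:
    ks = sorted(dist.counts)
    pd.DataFrame({"k": ks, "n_nuclei": [dist.counts[k] for k in ks]}).to_csv(
        path, index=False
    )


def read_config(path) -> Dict[str, str]:
    """Plain-text ``key: value`` configuration; '#' starts a comment."""
    out: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
        key, value = line.split(":", 1)
        out[key.strip()] = value.strip()
    return out


def read_stack(path, sidecar: Optional[str] = None) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    """Read a TIFF stack and its physical voxel size.

    The voxel size comes from a sidecar config file (default:
    ``<path>.meta``) with keys ``voxel_size_z_nm``, ``voxel_size_y_nm``,
    ``voxel_size_x_nm``; it is required, never inferred from the file.
    Returns ``(zyx array, (z, y, x) voxel size in µm)``.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        dtypes = {page.dtype for page in tf.pages}
        if len(dtypes) > 1:
            raise ValueError(f"{path}: mixed page dtypes {sorted(map(str, dtypes))}")
        arr = tf.asarray()
    if arr.ndim == 2:
        warnings.warn(f"{path}: single-page file treated as a one-slice stack")
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 3D (ZYX) stack, got shape {arr.shape}")

    sidecar_path = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".meta")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"voxel size metadata not found: create {sidecar_path} with lines "
            "'voxel_size_z_nm: ...', 'voxel_size_y_nm: ...', 'voxel_size_x_nm: ...'"
        )
    meta = read_config(sidecar_path)
    try:
        voxel_um = tuple(
            float(meta[f"voxel_size_{ax}_nm"]) / 1000.0 for ax in ("z", "y", "x")
        )
    except KeyError as exc:
        raise KeyError(f"{sidecar_path}: missing voxel size key {exc}") from exc
    if any(v <= 0 for v in voxel_um):
        raise ValueError(f"{sidecar_path}: voxel sizes must be positive, got {voxel_um}")
    return arr, voxel_um


def write_stack(stack: np.ndarray, path, voxel_size_nm: Sequence[float]) -> None:
    """Write a ZYX stack as multi-page TIFF plus the voxel-size sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")
    lines = [
        f"voxel_size_{ax}_nm: {float(v)}"
        for ax, v in zip(("z", "y", "x"), voxel_size_nm)
    ]
    path.with_suffix(path.suffix + ".meta").write_text("\n".join(lines) + "\n")


def write_provenance(path, params: Mapping[str, object]) -> None:
    """Write the resolved run configuration as a JSON sidecar."""
    from . import __version__

    resolved = {k: params[k] for k in sorted(params)}
    blob = json.dumps(resolved, sort_keys=True, default=str)
    doc = {
        "package": "meioquant",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "params": resolved,
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")
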