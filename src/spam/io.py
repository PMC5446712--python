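"""File I/O: images, boundary points, manifests, configs and result bundles."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .permtest import PermutationResult, StudyDesign
from .unwarp import VesselMap

__all__ = [
    "read_image",
    "write_image",
    "read_boundary_points",
    "write_boundary_points",
    "write_vessel_map",
    "read_vessel_map",
    "read_manifest_design",
    "save_result_bundle",
]


def read_image(path, channel: int | None = None) -> np.ndarray:
    """Read a TIFF or PNG image as a float 2D grid.

    Integer inputs are promoted losslessly to float64.  Multi-channel images
    require an explicit ``channel``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path.name} has {arr.shape[-1]} channels; select one with channel="
            )
        arr = arr[..., channel]
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2D image, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_image(path, values: np.ndarray) -> None:
    """Write a 2D array as 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float32))


def read_boundary_points(path) -> tuple[np.ndarray, np.ndarray]:
    """Read marked wall points for the two vessel boundaries.

    CSV needs columns ``wall`` (A|B), ``order``, ``x``, ``y``; JSON is
    ``{"A": [[x, y], ...], "B": [[x, y], ...]}``.  Coordinates are 0-based
    pixels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return np.asarray(data["A"], dtype=float), np.asarray(data["B"], dtype=float)
    df = pd.read_csv(path)
    missing = {"wall", "order", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    out = []
    for wall in ("A", "B"):
        sub = df[df["wall"] == wall].sort_values("order")
        if sub.empty:
            raise ValueError(f"{path.name}: no points for wall {wall}")
        out.append(sub[["x", "y"]].to_numpy(dtype=float))
    return out[0], out[1]


def write_boundary_points(path, points_a: np.ndarray, points_b: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(
            json.dumps(
                {"A": np.asarray(points_a).tolist(), "B": np.asarray(points_b).tolist()}
            )
        )
        return
    rows = []
    for wall, pts in (("A", points_a), ("B", points_b)):
        for k, (x, y) in enumerate(np.asarray(pts, dtype=float)):
            rows.append({"wall": wall, "order": k, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_vessel_map(base_path, vmap: VesselMap) -> None:
    """Write a map as float TIFF + CSV with a JSON metadata sidecar."""
    base = Path(base_path)
    write_image(base.with_suffix(".tif"), vmap.values)
    np.savetxt(base.with_suffix(".csv"), vmap.values, delimiter=",")
    meta = {
        "section_offsets": vmap.section_offsets.tolist(),
        "normalization_factor": float(vmap.normalization_factor),
        **vmap.metadata,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_vessel_map(base_path) -> VesselMap:
    base = Path(base_path)
    values = tifffile.imread(base.with_suffix(".tif")).astype(np.float64)
    meta_path = base.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        offsets = np.asarray(meta.pop("section_offsets", [0]), dtype=int)
        factor = float(meta.pop("normalization_factor", 1.0))
        return VesselMap(values, offsets, factor, meta)
    return VesselMap(values, np.array([0]), 1.0)


def read_manifest_design(manifest_path, paired: bool = False) -> StudyDesign:
    """Build a study design from a CSV manifest.

    Columns: ``map_path`` (TIFF, relative paths resolved against the
    manifest), ``group`` (A|B), and ``subject_id`` (required when paired;
    pairs are matched on it).
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = {"map_path", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")

    def load(row):
        p = Path(row["map_path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        return tifffile.imread(p).astype(np.float64)

    a_rows = df[df["group"] == "A"]
    b_rows = df[df["group"] == "B"]
    if a_rows.empty or b_rows.empty:
        raise ValueError("manifest must contain maps for both groups A and B")
    group_a = [load(r) for _, r in a_rows.iterrows()]
    group_b = [load(r) for _, r in b_rows.iterrows()]
    pair_index = None
    if paired:
        if "subject_id" not in df.columns:
            raise ValueError("paired design requires a subject_id column")
        b_by_subject = {r["subject_id"]: i for i, (_, r) in enumerate(b_rows.iterrows())}
        try:
            pair_index = [b_by_subject[r["subject_id"]] for _, r in a_rows.iterrows()]
        except KeyError as e:
            raise ValueError(f"no group-B map for subject {e.args[0]}") from e
    return StudyDesign(group_a, group_b, paired=paired, pair_index=pair_index)


def save_result_bundle(result: PermutationResult, out_dir) -> None:
    """Write result maps as TIFFs plus a JSON of parameters and distributions."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(out / "mean_diff.tif", result.mean_diff)
    write_image(out / "sd.tif", result.sd_map)
    write_image(out / "normalized_diff.tif", result.normalized_diff)
    if result.enhanced_diff is not None:
        write_image(out / "enhanced_diff.tif", result.enhanced_diff)
    write_image(out / "significance_mask.tif", result.significance_mask.astype(np.float32))
    info = {
        "alpha": result.alpha,
        "t_upper": result.t_upper,
        "t_lower": result.t_lower,
        "n_permutations": result.n_permutations,
        "seed": result.seed,
        "paired": result.paired,
        "n_a": result.n_a,
        "n_b": result.n_b,
        "used_tfce": result.used_tfce,
        "include_original_in_sd": result.include_original_in_sd,
        "n_significant_positive": result.n_significant[0],
        "n_significant_negative": result.n_significant[1],
        "max_distribution": result.distributions.max_values.tolist(),
        "min_distribution": result.distributions.min_values.tolist(),
    }
    if result.tfce_params is not None:
        info["tfce_params"] = {
            "E": result.tfce_params.E,
            "H": result.tfce_params.H,
            "n_levels": result.tfce_params.n_levels,
            "connectivity": result.tfce_params.connectivity,
        }
    (out / "result.json").write_text(json.dumps(info, indent=2))
    (out / "summary.txt").write_text(result.summary() + "\n")
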