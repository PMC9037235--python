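"""File formats: TIFF images and label maps, CSV tables, paired counts.

Round-trip fidelity is the contract: writing then reading reproduces
grids and tables exactly.  Label TIFFs carry the {0 background, 1 cell,
2 pit} code contract as 8-bit grayscale; intensity images are written as
16-bit grayscale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .agreement import PairedMeasurements
from .metrics import SampleResult
from .postprocess import CellRecord, ObjectTable
from .types import CLASS_CODES, DICImage, LabelMap

__all__ = [
    "read_image",
    "write_image",
    "read_labels",
    "write_labels",
    "write_table",
    "read_table",
    "read_pairs",
    "write_pairs",
    "write_instances",
    "sample_result_row",
    "write_sample_results",
]

TABLE_COLUMNS = [
    "cell_id",
    "area_um2",
    "solidity",
    "centroid_row",
    "centroid_col",
    "touches_edge",
    "pit_count",
    "pit_areas_um2",
    "pit_area_sum_um2",
    "status",
]

PAIR_COLUMNS = ["sample_id", "manual_percent_pit", "automated_percent_pit"]

RESULT_COLUMNS = [
    "sample_id",
    "n_cells_counted",
    "n_pitted",
    "percent_pit",
    "mean_pits_per_pitted_cell",
    "max_pits_in_one_cell",
    "mean_pit_size_percent_of_cell",
    "excluded_size",
    "excluded_edge",
    "excluded_solidity",
    "sufficient_count",
    "spleen_status",
]


def read_image(path, pixel_size_um: float) -> DICImage:
    """Read a grayscale TIFF/PNG as a DICImage scaled to [0, 1].

    Integer images are scaled by their dtype range; the pixel size is not
    stored in the file and must be supplied.
    """
    arr = tifffile.imread(path) if str(path).lower().endswith((".tif", ".tiff")) else _read_any(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    return DICImage(arr, pixel_size_um)


def _read_any(path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def write_image(image: DICImage, path) -> None:
    """Write the intensity grid as 16-bit grayscale TIFF."""
    arr = np.clip(image.intensity, 0.0, 1.0)
    tifffile.imwrite(path, np.round(arr * 65535).astype(np.uint16))


def write_labels(labels: LabelMap, path) -> None:
    """Write a label map as 8-bit TIFF with codes {0, 1, 2}."""
    tifffile.imwrite(path, labels.codes.astype(np.uint8))


def read_labels(path) -> LabelMap:
    """Read an 8-bit label TIFF, validating the {0, 1, 2} code contract."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: label map must be 2-D, got shape {arr.shape}")
    bad = np.setdiff1d(np.unique(arr), np.array(CLASS_CODES))
    if bad.size:
        raise ValueError(
            f"{path}: label map contains invalid code {int(bad[0])}; allowed codes are 0, 1, 2"
        )
    return LabelMap(arr.astype(np.uint8))


def write_instances(instances: np.ndarray, path) -> None:
    """Write instance labels as 16-bit TIFF."""
    tifffile.imwrite(path, np.asarray(instances).astype(np.uint16))


def table_to_frame(table: ObjectTable) -> pd.DataFrame:
    rows = []
    for r in table.records:
        rows.append(
            {
                "cell_id": r.cell_id,
                "area_um2": r.area_um2,
                "solidity": r.solidity,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
                "touches_edge": r.touches_edge,
                "pit_count": r.pit_count,
                "pit_areas_um2": ";".join(f"{a!r}" for a in r.pit_areas_um2),
                "pit_area_sum_um2": r.pit_area_sum_um2,
                "status": r.status,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_table(table: ObjectTable, path) -> None:
    """Write an ObjectTable as CSV, one row per cell, fixed column set."""
    table_to_frame(table).to_csv(path, index=False)


def read_table(path, pixel_size_um: float = float("nan"), source_image_id: str = "") -> ObjectTable:
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column {missing[0]!r}")
    records = []
    for _, row in df.iterrows():
        raw = row["pit_areas_um2"]
        areas = [float(a) for a in str(raw).split(";") if a] if pd.notna(raw) else []
        records.append(
            CellRecord(
                cell_id=int(row["cell_id"]),
                area_um2=float(row["area_um2"]),
                solidity=float(row["solidity"]),
                centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
                touches_edge=bool(row["touches_edge"]),
                pit_count=int(row["pit_count"]),
                pit_areas_um2=areas,
                status=str(row["status"]),
            )
        )
    return ObjectTable(records, source_image_id, "", pixel_size_um)


def read_pairs(path) -> PairedMeasurements:
    """Read paired manual/automated %PIT measurements from CSV."""
    df = pd.read_csv(path)
    for col in PAIR_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return PairedMeasurements(
        [str(s) for s in df["sample_id"]],
        df["manual_percent_pit"].to_numpy(dtype=np.float64),
        df["automated_percent_pit"].to_numpy(dtype=np.float64),
    )


def write_pairs(pairs: PairedMeasurements, path) -> None:
    pd.DataFrame(
        {
            "sample_id": pairs.sample_ids,
            "manual_percent_pit": pairs.manual,
            "automated_percent_pit": pairs.automated,
        }
    ).to_csv(path, index=False)


def sample_result_row(sample_id: str, result: SampleResult) -> dict:
    return {
        "sample_id": sample_id,
        "n_cells_counted": result.n_cells_counted,
        "n_pitted": result.n_pitted,
        "percent_pit": result.percent_pit,
        "mean_pits_per_pitted_cell": result.mean_pits_per_pitted_cell,
        "max_pits_in_one_cell": result.max_pits_in_one_cell,
        "mean_pit_size_percent_of_cell": result.mean_pit_size_percent_of_cell,
        "excluded_size": result.exclusions.get("excluded_size", 0),
        "excluded_edge": result.exclusions.get("excluded_edge", 0),
        "excluded_solidity": result.exclusions.get("excluded_solidity", 0),
        "sufficient_count": result.sufficient_count,
        "spleen_status": result.spleen_status.value if result.spleen_status else "",
    }


def write_sample_results(rows: list[dict], path, excel: bool = False) -> None:
    """Write per-sample results as CSV (optionally also as a spreadsheet,
    mirroring the macro's Excel export)."""
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, index=False)
    if excel:
        df.to_excel(str(path).rsplit(".", 1)[0] + ".xlsx", index=False)
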