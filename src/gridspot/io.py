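"""Reading images and coordinate labels; the partitioned dataset archive.

The archive is a single zip file of ``.npy`` members (numpy's own array
serialization) plus a ``metadata.json`` record: image stacks per split
and one variable-length coordinate table per image.  Members are written
with fixed zip timestamps, so identical content produces byte-identical
files — archives built from the same seed are reproducible down to the
byte.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DatasetArchive",
    "FORMAT_VERSION",
    "read_label_table",
    "load_image",
    "split_indices",
    "create_dataset",
    "save_archive",
    "load_archive",
]

FORMAT_VERSION = 1
SPLITS = ("train", "valid", "test")


@dataclass
class DatasetArchive:
    """Train/valid/test image stacks with ragged per-image labels."""

    x_train: np.ndarray
    y_train: list[np.ndarray]
    x_valid: np.ndarray
    y_valid: list[np.ndarray]
    x_test: np.ndarray
    y_test: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for split in SPLITS:
            x, y = self.images(split), self.labels(split)
            if x.ndim != 3:
                raise ValueError(f"x_{split} must be a (n, h, w) stack")
            if len(x) != len(y):
                raise ValueError(
                    f"x_{split} has {len(x)} images but y_{split} has "
                    f"{len(y)} label tables"
                )
            h, w = x.shape[1:]
            for i, coords in enumerate(y):
                coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
                if coords.size and (
                    (coords < 0).any()
                    or (coords[:, 0] >= h).any()
                    or (coords[:, 1] >= w).any()
                ):
                    raise ValueError(
                        f"label table {i} of split {split!r} has coordinates "
                        f"outside the {h}x{w} image"
                    )
                y[i] = coords

    def images(self, split: str) -> np.ndarray:
        return getattr(self, f"x_{split}")

    def labels(self, split: str) -> list[np.ndarray]:
        return getattr(self, f"y_{split}")

    @property
    def n_images(self) -> int:
        return sum(len(self.images(s)) for s in SPLITS)


def read_label_table(path, dialect: str = "plain") -> np.ndarray:
    """Read a coordinate CSV into an (n, 2) array of (row, col) floats.

    ``plain`` expects columns ``r,c`` in (row, col) pixel units, or the
    ``x,y`` layout written by :func:`gridspot.detect.write_coords_csv`
    (mapped y -> row, x -> col).  ``trackmate`` expects the 'All Spots
    statistics' export and maps POSITION_Y -> row, POSITION_X -> col,
    with no half-pixel shift (positions are taken as pixel units,
    calibration 1).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c).strip() for c in df.columns]
    if dialect == "plain":
        if "r" not in df.columns and {"x", "y"} <= set(df.columns):
            required = ("x", "y")
            row_col, col_col = "y", "x"
        else:
            required = ("r", "c")
            row_col, col_col = "r", "c"
    elif dialect == "trackmate":
        required = ("POSITION_X", "POSITION_Y")
        row_col, col_col = "POSITION_Y", "POSITION_X"
    else:
        raise ValueError(f"unknown label dialect {dialect!r}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        return np.empty((0, 2), dtype=np.float64)
    # TrackMate exports may carry non-numeric header rows below the header
    rows = pd.to_numeric(df[row_col], errors="raise").to_numpy(np.float64)
    cols = pd.to_numeric(df[col_col], errors="raise").to_numpy(np.float64)
    if not (np.isfinite(rows).all() and np.isfinite(cols).all()):
        raise ValueError(f"{path}: non-finite coordinate values")
    return np.column_stack([rows, cols])


def load_image(path) -> np.ndarray:
    """Load a single-plane TIFF or PNG as a 2D float64 array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        img = iio.imread(str(path))
    img = np.asarray(img)
    img = np.squeeze(img)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single 2D plane, got {img.shape}")
    return img.astype(np.float64)


def split_indices(n: int, fractions=(0.7, 0.15, 0.15), seed: int = 0,
                  strata=None) -> dict[str, np.ndarray]:
    """Deterministically partition ``range(n)`` into train/valid/test.

    Sizes: floor(n*f) for valid and test, remainder to train.  A split
    with nonzero fraction must receive at least one item.  When ``strata``
    (a per-item scalar, e.g. SNR) is given, items are binned into
    quantile classes and splits are stratified over those bins.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3:
        raise ValueError("fractions must be (train, valid, test)")
    if any(f < 0 for f in fractions) or not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must be non-negative and sum to 1")
    n_valid = int(np.floor(n * fractions[1]))
    n_test = int(np.floor(n * fractions[2]))
    n_train = n - n_valid - n_test
    for name, size, frac in (("train", n_train, fractions[0]),
                             ("valid", n_valid, fractions[1]),
                             ("test", n_test, fractions[2])):
        if frac > 0 and size == 0:
            raise ValueError(
                f"{n} images are too few for a nonzero {name!r} fraction "
                f"{frac}"
            )
    indices = np.arange(n)
    if strata is not None:
        from sklearn.model_selection import train_test_split

        strata = np.asarray(strata)
        if strata.shape != (n,):
            raise ValueError("strata must be a scalar per image")
        n_bins = max(1, min(10, n // 4))
        bins = pd.qcut(pd.Series(strata).rank(method="first"), n_bins,
                       labels=False).to_numpy()
        rest, test = _strat_split(indices, bins, n_test, seed)
        train, valid = _strat_split(rest, bins[rest], n_valid, seed + 1)
        return {"train": np.sort(train), "valid": np.sort(valid),
                "test": np.sort(test)}
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return {
        "train": np.sort(perm[:n_train]),
        "valid": np.sort(perm[n_train:n_train + n_valid]),
        "test": np.sort(perm[n_train + n_valid:]),
    }


def _strat_split(indices, bins, size, seed):
    if size == 0:
        return indices, np.array([], dtype=int)
    from sklearn.model_selection import train_test_split

    # stratification requires every class twice; fall back to plain split
    uniq, counts = np.unique(bins, return_counts=True)
    stratify = bins if counts.min() >= 2 and size >= len(uniq) else None
    rest, taken = train_test_split(indices, test_size=size,
                                   random_state=seed, stratify=stratify)
    return rest, taken


def create_dataset(image_paths, label_paths, split_fractions=(0.7, 0.15, 0.15),
                   seed: int = 0, dialect: str = "plain",
                   strata=None) -> DatasetArchive:
    """Pair images with label files by stem name and build an archive.

    Pairs are shuffled with ``seed`` and partitioned (floor for
    valid/test, remainder to train).  A label outside its image bounds is
    rejected with the offending file named.
    """
    image_paths = [Path(p) for p in image_paths]
    label_paths = [Path(p) for p in label_paths]
    if len(image_paths) != len(label_paths):
        raise ValueError(
            f"{len(image_paths)} images but {len(label_paths)} label files"
        )
    labels_by_stem = {p.stem: p for p in label_paths}
    if len(labels_by_stem) != len(label_paths):
        raise ValueError("duplicate label file stems")
    pairs = []
    for img_path in image_paths:
        if img_path.stem not in labels_by_stem:
            raise ValueError(f"no label file pairs with image {img_path.name!r}")
        pairs.append((img_path, labels_by_stem[img_path.stem]))

    images, tables = [], []
    for img_path, lbl_path in pairs:
        img = load_image(img_path)
        coords = read_label_table(lbl_path, dialect=dialect)
        h, w = img.shape
        if coords.size and (
            (coords < 0).any() or (coords[:, 0] >= h).any()
            or (coords[:, 1] >= w).any()
        ):
            raise ValueError(
                f"label file {lbl_path.name!r} has coordinates outside the "
                f"{h}x{w} image {img_path.name!r}"
            )
        images.append(img)
        tables.append(coords)
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise ValueError(f"all images must share one shape, got {shapes}")

    idx = split_indices(len(pairs), split_fractions, seed=seed, strata=strata)

    def stack(ii):
        if len(ii) == 0:
            return np.empty((0,) + images[0].shape, dtype=np.float32)
        return np.stack([images[i] for i in ii]).astype(np.float32)

    return DatasetArchive(
        x_train=stack(idx["train"]),
        y_train=[tables[i] for i in idx["train"]],
        x_valid=stack(idx["valid"]),
        y_valid=[tables[i] for i in idx["valid"]],
        x_test=stack(idx["test"]),
        y_test=[tables[i] for i in idx["test"]],
        metadata={
            "source": "gridspot.io.create_dataset",
            "n_images": len(pairs),
            "split_fractions": list(split_fractions),
            "split_seed": seed,
            "files": {s: [pairs[i][0].name for i in idx[s]] for s in SPLITS},
        },
    )


# -- archive serialization --------------------------------------------------

_FIXED_DATE = (1980, 1, 1, 0, 0, 0)


def _write_member(zf: zipfile.ZipFile, name: str, payload: bytes) -> None:
    info = zipfile.ZipInfo(name, date_time=_FIXED_DATE)
    info.compress_type = zipfile.ZIP_STORED
    info.external_attr = 0o600 << 16
    zf.writestr(info, payload)


def _npy_bytes(arr: np.ndarray) -> bytes:
    buf = _io.BytesIO()
    np.lib.format.write_array(buf, np.ascontiguousarray(arr),
                              allow_pickle=False)
    return buf.getvalue()


def save_archive(archive: DatasetArchive, path) -> None:
    """Persist an archive; identical content yields identical bytes."""
    meta = dict(archive.metadata)
    meta["format"] = "gridspot-dataset"
    meta["format_version"] = FORMAT_VERSION
    meta["n_labels"] = {s: len(archive.labels(s)) for s in SPLITS}
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        _write_member(
            zf, "metadata.json",
            json.dumps(meta, indent=2, sort_keys=True).encode(),
        )
        for split in SPLITS:
            _write_member(zf, f"x_{split}.npy",
                          _npy_bytes(archive.images(split).astype(np.float32)))
            for i, coords in enumerate(archive.labels(split)):
                _write_member(
                    zf, f"y_{split}_{i:05d}.npy",
                    _npy_bytes(np.asarray(coords, dtype=np.float64)),
                )


def load_archive(path) -> DatasetArchive:
    """Load an archive, verifying magic and format version."""
    try:
        zf = zipfile.ZipFile(path, "r")
    except zipfile.BadZipFile as exc:
        raise ValueError(f"{path}: not a dataset archive ({exc})") from exc
    with zf:
        names = set(zf.namelist())
        if "metadata.json" not in names:
            raise ValueError(f"{path}: not a gridspot dataset archive "
                             "(missing metadata.json)")
        meta = json.loads(zf.read("metadata.json"))
        if meta.get("format") != "gridspot-dataset":
            raise ValueError(f"{path}: not a gridspot dataset archive")
        version = meta.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported archive format version {version!r} "
                f"(expected {FORMAT_VERSION})"
            )

        def read_arr(name):
            if name not in names:
                raise ValueError(f"{path}: truncated archive, missing {name}")
            return np.lib.format.read_array(_io.BytesIO(zf.read(name)),
                                            allow_pickle=False)

        kwargs = {}
        for split in SPLITS:
            kwargs[f"x_{split}"] = read_arr(f"x_{split}.npy")
            n = meta["n_labels"][split]
            kwargs[f"y_{split}"] = [
                read_arr(f"y_{split}_{i:05d}.npy") for i in range(n)
            ]
    meta.pop("n_labels", None)
    meta.pop("format", None)
    meta.pop("format_version", None)
    return DatasetArchive(metadata=meta, **kwargs)
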