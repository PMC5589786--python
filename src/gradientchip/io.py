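"""File formats and run provenance: TIFF stacks, CSV tables, manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a multi-page grayscale TIFF as a (n_pages, H, W) array.

    Pages are returned in file order (one per time point).  RGB pages,
    mismatched page shapes or truncated files raise :class:`FormatError`
    naming the offending page.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = []
            shape = None
            for i, page in enumerate(tif.pages):
                arr = page.asarray()
                if arr.ndim != 2:
                    raise FormatError(f"page {i} of {path.name} is not grayscale (shape {arr.shape})")
                if shape is None:
                    shape = arr.shape
                elif arr.shape != shape:
                    raise FormatError(
                        f"page {i} of {path.name} has shape {arr.shape}, expected {shape}"
                    )
                pages.append(arr)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path.name}: {exc}") from exc
    if not pages:
        raise FormatError(f"{path.name} contains no pages")
    stack = np.stack(pages)
    return stack, {"n_pages": len(pages), "dtype": str(stack.dtype), "shape": stack.shape[1:]}


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (n_pages, H, W) array as a multi-page grayscale TIFF."""
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def config_hash(config_dict: dict) -> str:
    """Stable sha256 of a JSON-serializable configuration."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    """Provenance record sufficient to reproduce a pipeline run."""

    config_hash: str
    seed: int
    software_version: str
    started: str
    finished: str = ""
    stages: list = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict) -> None:
        self.stages.append({"stage": name, "outputs": {k: str(v) for k, v in outputs.items()}})

    def write(self, path) -> None:
        """Atomic write (temp file + rename) of the manifest JSON."""
        path = Path(path)
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                fh.write(payload)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise
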