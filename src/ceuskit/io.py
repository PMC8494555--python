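"""File formats and configuration.

Signals
    Binary ``.usig`` files: the 16-byte header (magic ``USIG``, version,
    kind, sample width, sample count, little-endian) followed by the samples
    as little-endian signed integers.  Any other extension is treated as
    delimited text, one sample per line.

Compressed containers
    ``.uqz`` files: 17-byte header (magic ``UQZ1``, algorithm byte,
    original length u64, CRC-32 u32, little-endian) followed by the
    byte-aligned payload.

Curves
    Two-column delimited text ``time,intensity`` with one header line.

Configuration
    YAML with nested sections; loaders below map sections onto the spec
    dataclasses.
"""

from __future__ import annotations

import hashlib
import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codec.container import ALGORITHMS, CompressedBlock
from .errors import FormatError
from .serialize import KIND_CODES, KIND_NAMES, pack_header, unpack_header, HEADER_SIZE
from .signal import Signal
from .synthetic import CohortSpec, DefectWaveSpec, GrassWaveSpec, PerfusionParams
from .tic import TICurve

_DTYPES = {8: "<i1", 16: "<i2", 32: "<i4"}


# ---------------------------------------------------------------------------
# signals


def write_signal(signal: Signal, path) -> None:
    path = Path(path)
    if path.suffix == ".usig":
        payload = signal.samples.astype(_DTYPES[signal.sample_width_bits]).tobytes()
        path.write_bytes(pack_header(signal) + payload)
    else:
        header = f"# ceuskit signal kind={signal.kind} width={signal.sample_width_bits}\n"
        path.write_text(header + "\n".join(str(int(v)) for v in signal.samples) + "\n")


def read_signal(path) -> Signal:
    path = Path(path)
    if path.suffix == ".usig":
        data = path.read_bytes()
        kind, width, count = unpack_header(data)
        expected = HEADER_SIZE + count * (width // 8)
        if len(data) != expected:
            raise FormatError(
                f"file is {len(data)} bytes, header implies {expected}",
                offset=min(len(data), expected),
            )
        samples = np.frombuffer(data, dtype=_DTYPES[width], offset=HEADER_SIZE)
        return Signal(samples=samples.astype(np.int64), kind=kind,
                      sample_width_bits=width, source_id=path.stem)
    kind, width = "other", 16
    values = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tokenised in line[1:].split():
                if tokenised.startswith("kind="):
                    kind = tokenised[5:]
                elif tokenised.startswith("width="):
                    width = int(tokenised[6:])
            continue
        values.append(int(line))
    return Signal(samples=np.asarray(values, dtype=np.int64), kind=kind,
                  sample_width_bits=width, source_id=path.stem)


# ---------------------------------------------------------------------------
# compressed container files

CONTAINER_MAGIC = b"UQZ1"
_CONTAINER = struct.Struct("<4sBQI")  # magic, algorithm, original_length, crc32
ALGO_CODES = {name: i for i, name in enumerate(ALGORITHMS)}


def write_container(block: CompressedBlock, path) -> None:
    header = _CONTAINER.pack(
        CONTAINER_MAGIC, ALGO_CODES[block.algorithm],
        block.original_length, block.checksum,
    )
    Path(path).write_bytes(header + block.payload)


def read_container(path) -> CompressedBlock:
    data = Path(path).read_bytes()
    if len(data) < _CONTAINER.size:
        raise FormatError("truncated container header", offset=len(data))
    magic, algo, length, crc = _CONTAINER.unpack_from(data)
    if magic != CONTAINER_MAGIC:
        raise FormatError(f"bad magic {magic!r}", offset=0)
    if algo >= len(ALGORITHMS):
        raise FormatError(f"unknown algorithm code {algo}", offset=4)
    return CompressedBlock(
        algorithm=ALGORITHMS[algo], payload=data[_CONTAINER.size :],
        original_length=length, checksum=crc,
    )


# ---------------------------------------------------------------------------
# curves and manifests


def write_curve(curve: TICurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("time,intensity\n")
        for t, y in zip(curve.times, curve.intensities):
            fh.write(f"{t:.6g},{y:.8g}\n")


def read_curve(path, window: float | None = None) -> TICurve:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns time,intensity")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    intensities = df.iloc[:, 1].to_numpy(dtype=float)
    if window is None:
        window = max(120.0, float(times[-1]))
    return TICurve(times=times, intensities=intensities,
                   roi_id=path.stem, window=window)


def read_manifest(path):
    """Manifest CSV with columns ``file,group``; paths relative to it."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    for col in ("file", "group"):
        if col not in df.columns:
            raise FormatError(f"manifest must have a {col!r} column")
    df["file"] = [str((path.parent / f)) for f in df["file"]]
    return df


# ---------------------------------------------------------------------------
# output tables with provenance footers


def write_table(df: pd.DataFrame, path, seed=None, config_digest: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        df.to_csv(fh, index=False)
        fh.write(
            f"# ceuskit {__version__} seed={seed} config={config_digest or 'none'}\n"
        )


# ---------------------------------------------------------------------------
# configuration


def config_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError("config root must be a mapping")
    return cfg


def grass_spec_from_config(cfg: dict) -> GrassWaveSpec:
    return GrassWaveSpec(**cfg.get("grass_wave", {}))


def defect_spec_from_config(cfg: dict) -> DefectWaveSpec:
    section = dict(cfg.get("defect_wave", {}))
    if "echo_amp_range" in section:
        section["echo_amp_range"] = tuple(section["echo_amp_range"])
    return DefectWaveSpec(**section)


def perfusion_params_from_config(section: dict) -> PerfusionParams:
    return PerfusionParams(**section)


def cohort_spec_from_config(cfg: dict, seed: int | None = None) -> CohortSpec:
    section = dict(cfg.get("cohort", {}))
    means = {
        label: perfusion_params_from_config(params)
        for label, params in section.pop("group_param_means", {}).items()
    }
    if seed is not None:
        section["seed"] = seed
    return CohortSpec(group_param_means=means, **section)
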