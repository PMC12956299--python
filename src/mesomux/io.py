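"""File formats and run configuration.

The native container for streams and per-pulse counts is HDF5 (open,
self-describing); images go out as 16-bit or floating-point multi-page
TIFF; configurations round-trip through JSON with a schema version.  Every
CLI run writes a manifest (effective config + seed + package version)
sufficient to reproduce its outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .gating import ChannelCounts, GateSet
from .synthetic import RawStream, ScopeConfig

__all__ = [
    "SCHEMA_VERSION",
    "CorruptStreamError",
    "RunConfig",
    "write_stream",
    "read_stream",
    "write_counts",
    "read_counts",
    "write_manifest",
]

SCHEMA_VERSION = 1


class CorruptStreamError(IOError):
    """The file is unreadable, truncated, or has an unexpected schema."""


def _scope_config_attrs(grp: h5py.Group, config: ScopeConfig) -> None:
    for f in dataclasses.fields(ScopeConfig):
        v = getattr(config, f.name)
        grp.attrs[f.name] = v if not isinstance(v, tuple) else list(v)


def _scope_config_from_attrs(grp: h5py.Group) -> ScopeConfig:
    kwargs = {}
    for f in dataclasses.fields(ScopeConfig):
        if f.name not in grp.attrs:
            continue
        v = grp.attrs[f.name]
        if isinstance(v, np.ndarray):
            v = tuple(float(x) for x in v)
        elif isinstance(v, np.generic):
            v = v.item()
        kwargs[f.name] = v
    return ScopeConfig(**kwargs)


def write_stream(path, stream: RawStream) -> None:
    """Persist a raw digitizer stream (waveform + event streams) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["content"] = "raw_stream"
        f.create_dataset("waveform", data=stream.waveform, compression="gzip")
        for name in ("laser_clock", "hsync1", "hsync2", "vsync"):
            f.create_dataset(name, data=getattr(stream, name))
        if stream.config is not None:
            _scope_config_attrs(f, stream.config)


def write_counts(path, counts: ChannelCounts, stream: RawStream | None = None) -> None:
    """Persist per-pulse channel counts (plus sync event tables) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["content"] = "channel_counts"
        f.attrs["channel_order"] = counts.channel_order
        f.attrs["accumulation"] = counts.accumulation
        f.create_dataset("counts", data=counts.values, compression="gzip")
        f.create_dataset("pulse_samples", data=counts.pulse_samples)
        if stream is not None:
            for name in ("hsync1", "hsync2", "vsync"):
                f.create_dataset(name, data=getattr(stream, name))


def _open_checked(path) -> h5py.File:
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise CorruptStreamError(f"cannot open {path}: {e}") from e
    version = f.attrs.get("schema_version")
    if version != SCHEMA_VERSION:
        f.close()
        raise CorruptStreamError(
            f"{path}: schema version {version!r} not supported "
            f"(expected {SCHEMA_VERSION})"
        )
    return f


def read_stream(path):
    """Read back a stream or counts container written by this package.

    Returns a :class:`RawStream` or ``(ChannelCounts, syncs)`` depending on
    the file's content tag; raises :class:`CorruptStreamError` on damaged
    or foreign files.
    """
    with _open_checked(path) as f:
        content = f.attrs.get("content")
        try:
            if content == "raw_stream":
                return RawStream(
                    waveform=f["waveform"][:],
                    laser_clock=f["laser_clock"][:],
                    hsync1=f["hsync1"][:],
                    hsync2=f["hsync2"][:],
                    vsync=f["vsync"][:],
                    config=_scope_config_from_attrs(f) if "sample_rate" in f.attrs else None,
                )
            if content == "channel_counts":
                counts = ChannelCounts(
                    values=f["counts"][:],
                    pulse_samples=f["pulse_samples"][:],
                    channel_order=str(f.attrs["channel_order"]),
                    accumulation=int(f.attrs["accumulation"]),
                )
                syncs = {
                    name: f[name][:] for name in ("hsync1", "hsync2", "vsync") if name in f
                }
                return counts, syncs
        except KeyError as e:
            raise CorruptStreamError(f"{path}: missing dataset {e}") from e
    raise CorruptStreamError(f"{path}: unknown content tag {content!r}")


read_counts = read_stream  # same dispatching reader


@dataclass
class RunConfig:
    """Bundle of every parameter a pipeline run needs; JSON round-trip."""

    scope: ScopeConfig = field(default_factory=ScopeConfig)
    gates: tuple[tuple[int, int], ...] = ((0, 7), (10, 17), (20, 27), (30, 37))
    record_len: int = 48
    accumulation: int = 1
    mixing_abc: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pixels_per_line: int = 64
    pulses_per_line: int = 256
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def gate_set(self) -> GateSet:
        return GateSet(gates=self.gates, record_len=self.record_len)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        version = d.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise CorruptStreamError(
                f"config schema version {version!r} not supported"
            )
        scope = ScopeConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.pop("scope").items()
        })
        d["gates"] = tuple(tuple(g) for g in d["gates"])
        d["mixing_abc"] = tuple(d["mixing_abc"])
        return cls(scope=scope, schema_version=SCHEMA_VERSION, **d)


def write_manifest(path, config: RunConfig, extra: dict | None = None) -> None:
    """Write the reproducibility manifest of a CLI run."""
    from . import __version__

    manifest = {
        "package": "mesomux",
        "version": __version__,
        "config": json.loads(config.to_json()),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2)
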