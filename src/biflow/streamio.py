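"""Self-describing text container for photon streams.

Format: a ``#``-prefixed header carrying the acquisition metadata, an
optional ``#TRUTH`` block with one CSV row per simulated particle, then
a CSV body with one row per photon (``macro_time_s, micro_time_ns,
channel``).  Floats are written with 17 significant digits so that
``read_stream(write_stream(s)) == s`` bit-for-bit.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .stream import AcquisitionConfig, ParticleTruth, PhotonStream

__all__ = ["write_stream", "read_stream"]

_MAGIC = "#BIFLOW-STREAM 1"
_G = "%.17g"


def _fmt(x: float) -> str:
    return _G % x


def write_stream(path: str | Path, stream: PhotonStream) -> None:
    """Write a stream (including any truth block) to ``path``."""
    cfg = stream.config
    lines = [
        _MAGIC,
        f"#sync_period_ns={_fmt(cfg.sync_period)}",
        f"#micro_window_ns={_fmt(cfg.micro_window)}",
        f"#adc_bins={cfg.adc_bins}",
        f"#bin_width_us={_fmt(cfg.bin_width)}",
        "#channels=" + ",".join(str(c) for c in cfg.channels),
        f"#seed={'' if stream.seed is None else stream.seed}",
        f"#n_records={len(stream)}",
    ]
    if stream.truth is not None:
        lines.append(f"#TRUTH n={len(stream.truth)}")
        lines.append(
            "#arrival_time_s,transit_fwhm_s,expected_photons,"
            "lifetimes_ns,fractions,channel_split"
        )
        for t in stream.truth:
            lines.append(
                "#"
                + ",".join(
                    [
                        _fmt(t.arrival_time),
                        _fmt(t.transit_fwhm),
                        _fmt(t.expected_photons),
                        ";".join(_fmt(x) for x in t.true_lifetimes),
                        ";".join(_fmt(x) for x in t.true_amplitude_fractions),
                        ";".join(_fmt(x) for x in t.channel_split),
                    ]
                )
            )
    lines.append("macro_time_s,micro_time_ns,channel")
    buf = io.StringIO()
    buf.write("\n".join(lines))
    buf.write("\n")
    for i in range(len(stream)):
        buf.write(
            f"{_fmt(stream.macro_times[i])},{_fmt(stream.micro_times[i])},"
            f"{stream.channels[i]}\n"
        )
    Path(path).write_text(buf.getvalue())


def _parse_header(lines: list[str]) -> tuple[dict, list[ParticleTruth] | None, int]:
    meta: dict = {}
    truth: list[ParticleTruth] | None = None
    i = 1
    while i < len(lines) and lines[i].startswith("#"):
        line = lines[i][1:]
        if line.startswith("TRUTH"):
            n_truth = int(line.split("n=")[1])
            truth = []
            i += 2  # skip the truth column-header comment
            for _ in range(n_truth):
                parts = lines[i][1:].split(",")
                truth.append(
                    ParticleTruth(
                        arrival_time=float(parts[0]),
                        transit_fwhm=float(parts[1]),
                        expected_photons=float(parts[2]),
                        true_lifetimes=tuple(
                            float(x) for x in parts[3].split(";")
                        ),
                        true_amplitude_fractions=tuple(
                            float(x) for x in parts[4].split(";")
                        ),
                        channel_split=tuple(float(x) for x in parts[5].split(";")),
                    )
                )
                i += 1
            continue
        key, _, val = line.partition("=")
        meta[key] = val
        i += 1
    return meta, truth, i


def read_stream(path: str | Path) -> PhotonStream:
    """Read a stream container written by :func:`write_stream`.

    Raises ``ValueError`` on a malformed header or non-monotone macro
    times (the :class:`PhotonStream` constructor enforces the latter).
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or lines[0] != _MAGIC:
        raise ValueError(f"{path}: not a biflow stream container (bad magic)")
    try:
        meta, truth, body_start = _parse_header(lines)
        config = AcquisitionConfig(
            sync_period=float(meta["sync_period_ns"]),
            micro_window=float(meta["micro_window_ns"]),
            adc_bins=int(meta["adc_bins"]),
            bin_width=float(meta["bin_width_us"]),
            channels=tuple(int(c) for c in meta["channels"].split(",")),
        )
        n_records = int(meta["n_records"])
        seed = int(meta["seed"]) if meta.get("seed") else None
    except (KeyError, ValueError, IndexError) as exc:
        raise ValueError(f"{path}: malformed stream header ({exc})") from exc
    if lines[body_start] != "macro_time_s,micro_time_ns,channel":
        raise ValueError(f"{path}: malformed record header line")
    if n_records:
        body = pd.read_csv(
            io.StringIO("\n".join(lines[body_start:])),
            dtype={"macro_time_s": np.float64, "micro_time_ns": np.float64,
                   "channel": np.int64},
            float_precision="round_trip",
        )
        if len(body) != n_records:
            raise ValueError(
                f"{path}: header announces {n_records} records, found {len(body)}"
            )
        macro = body["macro_time_s"].to_numpy()
        micro = body["micro_time_ns"].to_numpy()
        chan = body["channel"].to_numpy()
    else:
        macro = np.empty(0)
        micro = np.empty(0)
        chan = np.empty(0, dtype=np.int64)
    return PhotonStream(
        macro_times=macro,
        micro_times=micro,
        channels=chan,
        config=config,
        truth=truth,
        seed=seed,
    )
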