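"""Core data model and preprocessing for spectral-temporal photon histograms.

A spectral-temporal TCSPC measurement is a matrix of photon counts over
(spectral channel, arrival-time bin).  This module holds the container types,
the plain-text file dialect used throughout the package, and the preprocessing
steps applied to raw measurements before lifetime fitting: summing repeated
acquisitions, a peak-intensity quality-control gate, and aggregation of narrow
spectral channels into wide bands.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralTemporalHistogram",
    "InstrumentResponse",
    "BandDefinition",
    "DEFAULT_BANDS",
    "read_histogram",
    "write_histogram",
    "read_irf",
    "write_irf",
    "sum_replicates",
    "qc_filter",
    "aggregate_bands",
]

#: Column order of the histogram/IRF CSV dialect.
_COLUMNS = ["channel_index", "wavelength_nm", "bin_index", "time_ns", "counts"]

_GROUPS = {"normal", "abnormal", "reference", "simulated"}


@dataclass
class SpectralTemporalHistogram:
    """Photon counts over (spectral channel, time bin).

    Parameters
    ----------
    counts
        Array of shape ``(P, M)``; non-negative.  Observed (post-noise)
        histograms carry integer counts; clean simulated signals are
        real-valued.
    wavelengths_nm
        Strictly increasing channel-center wavelengths, length ``P``.
    bin_centers_ns
        Strictly increasing, uniformly spaced time-bin centers, length ``M``.
    label
        Free-text sample/location identifier.
    group
        One of ``normal``, ``abnormal``, ``reference``, ``simulated``.
    """

    counts: np.ndarray
    wavelengths_nm: np.ndarray
    bin_centers_ns: np.ndarray
    label: str = ""
    group: str = "simulated"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.bin_centers_ns = np.asarray(self.bin_centers_ns, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (channels x bins) array")
        p, m = self.counts.shape
        if self.wavelengths_nm.shape != (p,):
            raise ValueError(
                f"wavelengths_nm has length {self.wavelengths_nm.size}, "
                f"expected {p} (one per channel)"
            )
        if self.bin_centers_ns.shape != (m,):
            raise ValueError(
                f"bin_centers_ns has length {self.bin_centers_ns.size}, "
                f"expected {m} (one per time bin)"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if p > 1 and np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelengths_nm must be strictly increasing")
        diffs = np.diff(self.bin_centers_ns)
        if np.any(diffs <= 0):
            raise ValueError("bin_centers_ns must be strictly increasing")
        if m > 1 and not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {sorted(_GROUPS)}")

    @property
    def n_channels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def dt_ns(self) -> float:
        """Time-bin width in nanoseconds."""
        if self.n_bins < 2:
            raise ValueError("dt_ns undefined for a single-bin histogram")
        return float(self.bin_centers_ns[1] - self.bin_centers_ns[0])

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @property
    def peak_count(self) -> float:
        """Largest single (channel, bin) count — the 2-D peak intensity."""
        return float(self.counts.max())

    def with_counts(self, counts: np.ndarray) -> "SpectralTemporalHistogram":
        return replace(self, counts=np.asarray(counts, dtype=float))


@dataclass
class InstrumentResponse:
    """Per-channel instrument response function on the histogram grid.

    The observed decay is the true fluorescence decay convolved with this
    response.  ``normalized`` records whether each channel's response has
    been scaled to unit sum (required before deconvolution fitting).
    """

    response: np.ndarray
    bin_centers_ns: np.ndarray
    wavelengths_nm: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.bin_centers_ns = np.asarray(self.bin_centers_ns, dtype=float)
        if self.response.ndim == 1:
            self.response = self.response[None, :]
        if np.any(self.response < 0):
            raise ValueError("IRF must be non-negative")
        if self.wavelengths_nm is not None:
            self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.response.shape[0]

    @property
    def n_bins(self) -> int:
        return self.response.shape[1]

    def normalize(self) -> "InstrumentResponse":
        """Return a copy with each channel's response summing to 1."""
        sums = self.response.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("cannot normalize an all-zero IRF channel")
        return InstrumentResponse(
            response=self.response / sums,
            bin_centers_ns=self.bin_centers_ns,
            wavelengths_nm=self.wavelengths_nm,
            normalized=True,
        )

    def for_histogram(self, h: SpectralTemporalHistogram) -> np.ndarray:
        """Return a (P, M) response matrix matched to histogram ``h``.

        A single-channel IRF is broadcast across all channels of ``h``.
        """
        if self.n_bins != h.n_bins:
            raise ValueError(
                f"IRF has {self.n_bins} bins, histogram has {h.n_bins}"
            )
        if self.n_channels == 1:
            return np.broadcast_to(self.response, h.counts.shape)
        if self.n_channels != h.n_channels:
            raise ValueError(
                f"IRF has {self.n_channels} channels, histogram has {h.n_channels}"
            )
        return self.response


@dataclass(frozen=True)
class BandDefinition:
    """A wide spectral band: channels with lower_nm <= wavelength <= upper_nm."""

    lower_nm: float
    upper_nm: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.lower_nm < self.upper_nm:
            raise ValueError("band requires lower_nm < upper_nm")

    def member_mask(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        w = np.asarray(wavelengths_nm)
        return (w >= self.lower_nm) & (w <= self.upper_nm)


#: The two 40 nm bands used for aggregated-lifetime (AFL) analysis.  A
#: one-channel-wide gap separates them; the bands do not overlap.
DEFAULT_BANDS = (
    BandDefinition(557.13, 597.42, name="557.13-597.42nm"),
    BandDefinition(597.93, 638.22, name="597.93-638.22nm"),
)


# ---------------------------------------------------------------------------
# File I/O: long-format CSV + optional key-value sidecar metadata
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta")


def write_histogram(h: SpectralTemporalHistogram, path: str | Path) -> None:
    """Write a histogram in the long-format CSV dialect plus a metadata sidecar."""
    path = Path(path)
    p, m = h.counts.shape
    ch = np.repeat(np.arange(p), m)
    bn = np.tile(np.arange(m), p)
    df = pd.DataFrame(
        {
            "channel_index": ch,
            "wavelength_nm": h.wavelengths_nm[ch],
            "bin_index": bn,
            "time_ns": h.bin_centers_ns[bn],
            "counts": h.counts.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = _sidecar_path(path)
    meta.write_text(
        f"label={h.label}\ngroup={h.group}\ndt_ns={h.dt_ns!r}\n"
        if m > 1
        else f"label={h.label}\ngroup={h.group}\n"
    )


def _read_long_csv(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    dup = df.duplicated(subset=["channel_index", "bin_index"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ValueError(f"{path}: duplicate (channel_index, bin_index) at row {row}")
    neg = df["counts"] < 0
    if neg.any():
        row = int(df.index[neg][0])
        raise ValueError(f"{path}: negative count at row {row}")
    df = df.sort_values(["channel_index", "bin_index"], kind="stable")
    p = int(df["channel_index"].max()) + 1
    m = int(df["bin_index"].max()) + 1
    if len(df) != p * m:
        raise ValueError(f"{path}: expected a complete {p}x{m} grid, got {len(df)} rows")
    counts = df["counts"].to_numpy().reshape(p, m)
    wavelengths = df["wavelength_nm"].to_numpy().reshape(p, m)[:, 0]
    times = df["time_ns"].to_numpy().reshape(p, m)[0, :]
    tgrid = df["time_ns"].to_numpy().reshape(p, m)
    if not np.allclose(tgrid, times[None, :]):
        raise ValueError(f"{path}: time grid differs across channels")
    if m > 1:
        diffs = np.diff(times)
        if np.any(diffs <= 0) or not np.allclose(diffs, diffs[0], rtol=1e-6):
            raise ValueError(f"{path}: non-uniform time grid")
    return counts, wavelengths, times


def _read_sidecar(path: Path) -> dict[str, str]:
    meta = _sidecar_path(path)
    out: dict[str, str] = {}
    if meta.exists():
        for line in meta.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                out[k.strip()] = v.strip()
    return out


def read_histogram(path: str | Path) -> SpectralTemporalHistogram:
    """Read a histogram written by :func:`write_histogram`.

    Round-trips exactly: counts and both axes are reconstructed as stored.
    The wavelength grid is taken from the file, never recomputed.
    """
    path = Path(path)
    counts, wavelengths, times = _read_long_csv(path)
    meta = _read_sidecar(path)
    return SpectralTemporalHistogram(
        counts=counts,
        wavelengths_nm=wavelengths,
        bin_centers_ns=times,
        label=meta.get("label", path.stem),
        group=meta.get("group", "simulated"),
    )


def write_irf(irf: InstrumentResponse, path: str | Path) -> None:
    """Write an IRF using the same long-format dialect as histograms."""
    path = Path(path)
    p, m = irf.response.shape
    if irf.wavelengths_nm is not None:
        wl = irf.wavelengths_nm
    else:
        wl = np.arange(p, dtype=float)
    ch = np.repeat(np.arange(p), m)
    bn = np.tile(np.arange(m), p)
    pd.DataFrame(
        {
            "channel_index": ch,
            "wavelength_nm": wl[ch],
            "bin_index": bn,
            "time_ns": irf.bin_centers_ns[bn],
            "counts": irf.response.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_irf(path: str | Path, normalize: bool = True) -> InstrumentResponse:
    """Read an IRF; by default normalize each channel to unit sum at load."""
    counts, wavelengths, times = _read_long_csv(Path(path))
    irf = InstrumentResponse(
        response=counts, bin_centers_ns=times, wavelengths_nm=wavelengths
    )
    return irf.normalize() if normalize else irf


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def _check_axes_match(a: SpectralTemporalHistogram, b: SpectralTemporalHistogram) -> None:
    if a.counts.shape != b.counts.shape:
        raise ValueError(
            f"histogram shapes differ: {a.counts.shape} vs {b.counts.shape}"
        )
    if not np.allclose(a.wavelengths_nm, b.wavelengths_nm):
        raise ValueError("wavelength axes differ between replicates")
    if not np.allclose(a.bin_centers_ns, b.bin_centers_ns):
        raise ValueError("time axes differ between replicates")


def sum_replicates(
    replicates: Sequence[SpectralTemporalHistogram],
) -> SpectralTemporalHistogram:
    """Sum repeated acquisitions of one location element-wise.

    Repeated measurements at a location are summed before any further
    assessment to improve signal-to-noise; the total photon count is
    conserved exactly.
    """
    replicates = list(replicates)
    if not replicates:
        raise ValueError("need at least one replicate")
    first = replicates[0]
    for other in replicates[1:]:
        _check_axes_match(first, other)
    total = np.sum([r.counts for r in replicates], axis=0)
    return replace(first, counts=total)


def qc_filter(h: SpectralTemporalHistogram, threshold: float = 300) -> bool:
    """Quality-control gate on summed histograms.

    Returns True (pass) iff the peak intensity — the maximum single
    (channel, bin) count — is at least ``threshold``.  Histograms with a
    peak strictly below the threshold carry too little signal for reliable
    lifetime fitting and are excluded.  A peak exactly at the threshold
    passes.
    """
    return h.peak_count >= threshold


def aggregate_bands(
    h: SpectralTemporalHistogram,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
) -> SpectralTemporalHistogram:
    """Aggregate narrow spectral channels into wide bands.

    Each output "channel" is one band; its per-bin counts are the sums over
    all member channels (``lower_nm <= wavelength <= upper_nm``).  The output
    wavelength axis carries the band midpoints.  When the bands tile all
    channels the total photon count is conserved exactly.
    """
    bands = list(bands)
    if not bands:
        raise ValueError("need at least one band")
    rows = []
    centers = []
    for band in bands:
        mask = band.member_mask(h.wavelengths_nm)
        if not mask.any():
            raise ValueError(
                f"band {band.name or (band.lower_nm, band.upper_nm)} "
                "contains zero channels"
            )
        rows.append(h.counts[mask].sum(axis=0))
        centers.append(0.5 * (band.lower_nm + band.upper_nm))
    order = np.argsort(centers)
    return SpectralTemporalHistogram(
        counts=np.asarray(rows)[order],
        wavelengths_nm=np.asarray(centers)[order],
        bin_centers_ns=h.bin_centers_ns,
        label=h.label,
        group=h.group,
    )
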