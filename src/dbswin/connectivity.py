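"""STN-cortex coherence features and feature-table assembly.

Coherence between an STN contact channel and each of 30 cortical parcel
channels is estimated with the multitaper method (DPSS tapers, +/-2 Hz
half-bandwidth on 2 s epochs), averaged within the seven frequency bands,
spatially z-scored across parcels, and hemisphere-aligned so that columns
are expressed relative to the electrode (after alignment, ``_R`` parcels are
ipsilateral and ``_L`` parcels contralateral to the recording electrode).
The full feature table holds 7 STN power features plus 30 x 7 = 210
coherence features per contact (217 electrophysiological columns), with an
optional anatomical sweet-spot distance column.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import windows

from .spectra import (
    EPOCH_SECONDS,
    FMAX,
    FMIN,
    BandScheme,
    EpochedRecording,
    stn_band_features,
)

__all__ = [
    "PARCEL_PAIRS",
    "PARCELS",
    "PARCEL_LOBES",
    "SWEET_SPOT_MNI",
    "CoherenceMap",
    "band_coherence",
    "coherence_matrix",
    "spatial_zscore",
    "mirror_hemispheres",
    "ring_mode_features",
    "sweetspot_distance",
    "assemble_features",
    "extract_feature_table",
    "FEATURE_SUBSETS",
]

# 15 homologous left/right parcel pairs with lobe labels; lobe membership
# drives the importance normalization and the reduced feature subsets.
PARCEL_PAIRS: list[tuple[str, str]] = [
    ("precentral", "sensorimotor"),
    ("postcentral", "sensorimotor"),
    ("superior_frontal", "frontal"),
    ("middle_frontal", "frontal"),
    ("medial_frontal", "frontal"),
    ("superior_parietal", "parietal"),
    ("inferior_parietal", "parietal"),
    ("precuneus", "parietal"),
    ("superior_temporal", "temporal"),
    ("middle_temporal", "temporal"),
    ("inferior_temporal", "temporal"),
    ("superior_occipital", "occipital"),
    ("middle_occipital", "occipital"),
    ("cerebellum_anterior", "cerebellum"),
    ("cerebellum_posterior", "cerebellum"),
]

PARCELS: list[str] = [f"{base}_{h}" for base, _ in PARCEL_PAIRS for h in ("L", "R")]
PARCEL_LOBES: dict[str, str] = {
    f"{base}_{h}": lobe for base, lobe in PARCEL_PAIRS for h in ("L", "R")
}

#: published stereotactic sweet spot for STN DBS (right hemisphere), mm
SWEET_SPOT_MNI = np.array([12.58, -13.41, -5.87])

#: multitaper half-bandwidth (Hz) on a 2 s epoch -> NW = 4, 7 DPSS tapers
MT_HALF_BANDWIDTH = 2.0

FEATURE_SUBSETS = (
    "full", "stn_only", "coherence_only", "no_cerebellum",
    "sensorimotor_only", "enhanced",
)


@dataclass
class CoherenceMap:
    """Per-parcel band coherence for one contact.

    ``values``: frame indexed by parcel, one column per band.  Raw maps are
    magnitude-squared coherence in [0, 1]; z-scored maps have parcel-mean 0
    and parcel-sd 1 per band.
    """

    values: pd.DataFrame
    zscored: bool = False

    def __post_init__(self) -> None:
        if not self.zscored:
            v = self.values.to_numpy()
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
                raise ValueError("raw coherence must lie in [0, 1]")


def _tapered_fft(data: np.ndarray, fs: float):
    """DPSS-tapered epoch FFTs: (n_channels, n_epochs, n_tapers, n_freqs).

    Epochs are non-overlapping 2 s windows, so the per-epoch cross-spectral
    estimates averaged by the coherence estimator are independent and the
    small-sample coherence bias is 1/(n_epochs * n_tapers).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    nper = int(round(EPOCH_SECONDS * fs))
    n_epochs = data.shape[1] // nper
    if n_epochs < 1:
        raise ValueError("need at least one full 2 s epoch")
    nw = MT_HALF_BANDWIDTH * EPOCH_SECONDS
    n_tapers = int(2 * nw - 1)
    tapers = windows.dpss(nper, nw, Kmax=n_tapers)  # (T, nper)
    x = data[:, : n_epochs * nper].reshape(data.shape[0], n_epochs, nper)
    x = x - x.mean(axis=-1, keepdims=True)
    # (C, E, 1, nper) * (T, nper) -> (C, E, T, nper)
    tapered = x[:, :, None, :] * tapers[None, None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    return spec, freqs


_INT_CACHE: dict = {}


def _integer_bins(freqs: np.ndarray):
    key = (freqs.size, float(freqs[1]) if freqs.size > 1 else 0.0)
    if key not in _INT_CACHE:
        idx = np.nonzero(
            np.isclose(freqs % 1.0, 0.0) & (freqs >= FMIN) & (freqs <= FMAX)
        )[0]
        _INT_CACHE[key] = (idx, np.round(freqs[idx]).astype(int))
    return _INT_CACHE[key]


def coherence_matrix(
    x: np.ndarray, y: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence between two channel sets.

    Returns ``(msc, freqs)`` with ``msc`` of shape (n_x, n_y, n_freqs) at
    integer frequencies 1-300 Hz.  Cross- and auto-spectra are averaged over
    epochs and DPSS tapers before forming the coherence.
    """
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    if x.shape[-1] != y.shape[-1]:
        raise ValueError("signals must have equal length")
    if np.any(x.std(axis=-1) == 0) or np.any(y.std(axis=-1) == 0):
        raise ValueError("zero-variance input channel")
    sx, freqs = _tapered_fft(x, fs)
    sy, _ = _tapered_fft(y, fs)
    idx, int_freqs = _integer_bins(freqs)
    sx = sx[..., idx]
    sy = sy[..., idx]
    sxx = np.mean(np.abs(sx) ** 2, axis=(1, 2))  # (n_x, F)
    syy = np.mean(np.abs(sy) ** 2, axis=(1, 2))  # (n_y, F)
    sxy = np.einsum("xetf,yetf->xyf", sx, np.conj(sy)) / (
        sx.shape[1] * sx.shape[2]
    )
    msc = np.abs(sxy) ** 2 / (sxx[:, None, :] * syy[None, :, :])
    return np.clip(msc, 0.0, 1.0), int_freqs


def band_coherence(
    x: np.ndarray, y: np.ndarray, fs: float, scheme: BandScheme | None = None
) -> np.ndarray:
    """Band-averaged coherence between two signals, one value per band."""
    scheme = scheme or BandScheme()
    msc, freqs = coherence_matrix(x, y, fs)
    out = np.empty(len(scheme.bands))
    for i, (lo, hi) in enumerate(scheme.bands.values()):
        sel = (freqs >= lo) & (freqs <= hi)
        out[i] = msc[0, 0, sel].mean()
    return out


def spatial_zscore(m: CoherenceMap) -> CoherenceMap:
    """Z-score coherence across parcels, per band (sd with n-1)."""
    if m.zscored:
        raise ValueError("map already z-scored")
    sd = m.values.std(axis=0, ddof=1)
    scale = np.maximum(np.abs(m.values.mean(axis=0).to_numpy()), 1.0)
    if np.any(sd.to_numpy() <= 1e-12 * scale):
        raise ValueError("zero coherence variance across parcels")
    z = (m.values - m.values.mean(axis=0)) / sd
    return CoherenceMap(values=z, zscored=True)


def _partner(parcel: str) -> str:
    if parcel.endswith("_L"):
        return parcel[:-2] + "_R"
    if parcel.endswith("_R"):
        return parcel[:-2] + "_L"
    raise ValueError(f"parcel {parcel!r} has no hemisphere suffix")


def mirror_hemispheres(m: CoherenceMap, side: str) -> CoherenceMap:
    """Align a coherence map across the mid-sagittal plane.

    For left-implanted electrodes every left/right parcel pair swaps values,
    so that after alignment ``_R`` columns are ipsilateral and ``_L``
    columns contralateral to the electrode for every contact.  Right-side
    maps are returned unchanged.  Applying the operation twice restores the
    original map.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if side == "right":
        return replace(m)
    partners = [_partner(p) for p in m.values.index]
    missing = set(partners) - set(m.values.index)
    if missing:
        raise ValueError(f"unpaired parcels: {sorted(missing)}")
    swapped = m.values.loc[partners].copy()
    swapped.index = m.values.index
    return replace(m, values=swapped)


def ring_mode_features(segment_rows: pd.DataFrame) -> pd.Series:
    """Feature row of a ring-mode composite: element-wise mean of segments."""
    if len(segment_rows) < 2:
        raise ValueError("ring mode needs at least two segment rows")
    return segment_rows.mean(axis=0)


def sweetspot_distance(xyz, side: str) -> float:
    """Euclidean distance (mm) from a contact to the STN sweet spot.

    The published spot lies in the right hemisphere; its x coordinate is
    sign-flipped for left-side electrodes.
    """
    spot = SWEET_SPOT_MNI.copy()
    if side == "left":
        spot[0] = -spot[0]
    elif side != "right":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return float(np.linalg.norm(np.asarray(xyz, dtype=float) - spot))


def _coherence_columns(parcels, bands) -> list[str]:
    return [f"coh_{p}_{b}" for p in sorted(parcels) for b in bands]


def assemble_features(
    stn_bands: pd.DataFrame,
    coherence_maps: dict,
    anatomy: pd.Series | None = None,
    subset: str = "full",
    selected_features: list[str] | None = None,
    scheme: BandScheme | None = None,
) -> pd.DataFrame:
    """Build the contacts x features table for a named feature subset.

    ``stn_bands``: per-contact frame with columns ``stn_<band>``.
    ``coherence_maps``: contact key -> aligned, z-scored CoherenceMap.
    Subsets: ``full`` (217 columns), ``stn_only`` (7), ``coherence_only``
    (210), ``no_cerebellum``, ``sensorimotor_only`` (STN + sensorimotor
    parcels), ``enhanced`` (``selected_features`` + sweet-spot distance).
    """
    scheme = scheme or BandScheme()
    bands = scheme.names
    if subset not in FEATURE_SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; valid: {FEATURE_SUBSETS}")

    coh_rows = {}
    for key, cmap in coherence_maps.items():
        if not cmap.zscored:
            raise ValueError("coherence maps must be z-scored before assembly")
        row = {}
        for p in cmap.values.index:
            for b in bands:
                row[f"coh_{p}_{b}"] = cmap.values.loc[p, b]
        coh_rows[key] = row
    coh = pd.DataFrame.from_dict(coh_rows, orient="index")
    coh.index = pd.MultiIndex.from_tuples(coh.index, names=stn_bands.index.names)
    coh = coh.reindex(columns=_coherence_columns(PARCELS, bands))
    coh = coh.loc[stn_bands.index]

    stn_cols = [f"stn_{b}" for b in bands]
    stn = stn_bands.reindex(columns=stn_cols)
    full = pd.concat([stn, coh], axis=1)
    if full.isna().any().any():
        raise ValueError("missing values in assembled feature table")

    if subset == "full":
        return full
    if subset == "stn_only":
        return full[stn_cols]
    if subset == "coherence_only":
        return full[list(coh.columns)]
    if subset == "no_cerebellum":
        drop = [c for c in coh.columns
                if PARCEL_LOBES[_parcel_of(c)] == "cerebellum"]
        return full.drop(columns=drop)
    if subset == "sensorimotor_only":
        keep = stn_cols + [c for c in coh.columns
                           if PARCEL_LOBES[_parcel_of(c)] == "sensorimotor"]
        return full[keep]
    # enhanced: best electrophysiological features + anatomical distance
    if selected_features is None:
        raise ValueError("subset 'enhanced' requires selected_features")
    if anatomy is None:
        raise ValueError("subset 'enhanced' requires anatomy distances")
    missing = [f for f in selected_features if f not in full.columns]
    if missing:
        raise ValueError(f"unknown selected features: {missing}")
    out = full[list(selected_features)].copy()
    out["sweetspot_dist_mm"] = anatomy.loc[out.index]
    return out


def _parcel_of(column: str) -> str:
    # column format: coh_<parcel>_<band>; parcel itself contains underscores
    body = column[len("coh_"):]
    for p in PARCELS:
        if body.startswith(p + "_"):
            return p
    raise ValueError(f"no parcel label in column {column!r}")


def extract_feature_table(
    rec: EpochedRecording, scheme: BandScheme | None = None
) -> tuple[pd.DataFrame, dict]:
    """STN band powers and aligned z-scored coherence maps for one patient.

    Returns ``(stn_bands, coherence_maps)`` keyed/indexed by
    ``(patient_id, side, contact_id)``, ready for :func:`assemble_features`.
    """
    scheme = scheme or BandScheme()
    bands = scheme.names
    parcels = rec.parcel_labels
    parcel_data = rec.data[rec.parcel_index]

    stn_rows = {}
    cmaps: dict = {}
    for side in ("left", "right"):
        idx = rec.stn_index(side)
        if not idx:
            continue
        contact_data = rec.data[idx]
        msc, freqs = coherence_matrix(contact_data, parcel_data, rec.fs)
        band_sel = {b: (freqs >= lo) & (freqs <= hi)
                    for b, (lo, hi) in scheme.bands.items()}
        for row, ch in enumerate(idx):
            key = (rec.patient_id, side, rec.contact_ids[ch])
            stn_rows[key] = {
                f"stn_{b}": v
                for b, v in zip(bands, stn_band_features(rec.data[ch], rec.fs, scheme))
            }
            vals = pd.DataFrame(
                {b: msc[row, :, band_sel[b]].mean(axis=0) for b in bands},
                index=parcels,
            )
            cmap = mirror_hemispheres(
                spatial_zscore(CoherenceMap(values=vals)), side
            )
            cmaps[key] = cmap

    stn_df = pd.DataFrame.from_dict(stn_rows, orient="index")
    stn_df.index = pd.MultiIndex.from_tuples(
        stn_df.index, names=["patient_id", "side", "contact_id"]
    )
    return stn_df, cmaps
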