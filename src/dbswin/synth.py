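"""Synthetic cohorts for the contact-selection pipeline.

Each synthetic patient carries a bilateral DBS electrode (one electrode per
hemisphere) and 30 cortical parcel channels.  A latent per-contact quality
``q ~ N(0, 1)`` drives both the electrophysiology and the monopolar-review
thresholds, so that the true normalized therapeutic window is recoverable
from the signals:

* contact channels are 1/f background noise (log-power slope about -1.5)
  plus band-limited oscillations (alpha fixed; low-beta, high-gamma and HFO
  scaled by ``1 + quality_effect * q``) plus a 50 Hz line-noise sinusoid;
* each hemisphere has a band-limited (high-beta) common source mixed into
  three electrode-relative parcels (ipsilateral superior frontal and
  superior temporal, contralateral posterior cerebellum) and into every
  contact of that side with weight increasing in ``q`` -- the coherent
  STN-cortex coupling;
* review thresholds move with ``q`` (benefit earlier, side effects later),
  are quantized to the amplitude step, clipped to the tested range, and
  censored to "absent" when they exceed the highest amplitude tested (plus
  extra missingness at ``missing_rate``).

Oscillations are band-passed Gaussian noise rather than sinusoids so that
multitaper coherence behaves like it does on real data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .review import MonopolarReview, window_table
from .spectra import EPOCH_SECONDS, EpochedRecording

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_review",
    "bandlimited_noise",
    "pink_noise",
    "save_cohort",
    "load_reviews",
]

#: electrode-relative parcels receiving the common source ("I"=ipsi, "C"=contra)
COUPLED_PARCELS = [
    ("superior_frontal", "I"),
    ("superior_temporal", "I"),
    ("cerebellum_posterior", "C"),
]

#: coupling band of the shared STN-cortex source (high-beta), Hz
COUPLING_BAND = (21.0, 35.0)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults define the study conditions emulated."""

    n_patients: int = 20
    contacts_per_electrode: int = 8
    n_parcels: int = 30
    fs: float = 2000.0
    duration: float = 60.0  # seconds of resting-state signal per patient
    quality_effect: float = 1.0  # latent-quality coupling strength
    noise_sd: float = 0.3  # threshold noise, mA
    line_noise_amp: float = 0.5  # 50 Hz sinusoid amplitude, a.u.
    missing_rate: float = 0.1  # extra probability of an absent threshold
    amp_step: float = 0.5  # review amplitude step, mA
    amp_max: float = 5.0  # highest amplitude tested, mA
    seed: int = 0
    ring_mode: bool = False  # add ring-mode composites of segment levels
    # signal-model constants (a.u.); oscillation amplitudes are the baseline
    # scaled by (1 + quality_effect * q) for the quality-dependent bands
    background_sd: float = 1.0
    osc_amps: dict = field(
        default_factory=lambda: {
            "alpha": (8.0, 12.0, 0.25, False),
            "low_beta": (13.0, 20.0, 0.20, True),
            "high_gamma": (60.0, 90.0, 0.15, True),
            "hfo": (200.0, 300.0, 0.10, True),
        }
    )
    coupling_weight: float = 0.6  # contact-side mixing of the shared source
    parcel_coupling: float = 0.8  # parcel mixing of the shared source

    def __post_init__(self) -> None:
        if min(self.n_patients, self.contacts_per_electrode, self.n_parcels) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be a probability")
        if self.fs <= 600.0:
            raise ValueError("fs must exceed 600 Hz (HFO band below Nyquist)")
        if self.duration < EPOCH_SECONDS:
            raise ValueError("duration too short for one 2 s epoch")
        if self.amp_step <= 0 or self.amp_max <= self.amp_step:
            raise ValueError("need 0 < amp_step < amp_max")

    @property
    def amp_range(self) -> float:
        # lowest amplitude tested is one step
        return self.amp_max - self.amp_step


@dataclass
class SyntheticCohort:
    """Recordings, reviews and ground truth of one simulated cohort."""

    recordings: list
    reviews: list
    truth: pd.DataFrame  # per contact: q, coordinates, true window, chosen
    planted_features: list
    config: SimConfig


def pink_noise(n: int, rng: np.random.Generator, slope: float = -1.5) -> np.ndarray:
    """1/f noise with the given log-power slope, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (slope / 2.0)
    x = np.fft.irfft(spec * shaping, n)
    return x / x.std()


def bandlimited_noise(
    n: int, fs: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with power confined to [lo, hi] Hz, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _quantize_threshold(value: float, cfg: SimConfig):
    """First tested amplitude at which the effect appears, or None if censored."""
    step = cfg.amp_step
    q = math.ceil(value / step - 1e-9) * step
    if q > cfg.amp_max + 1e-9:
        return None  # no effect up to the highest amplitude tested
    return float(min(max(q, step), cfg.amp_max))


def generate_review(
    qualities: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    patient_id: str = "P00",
    side: str = "right",
    contact_ids: list | None = None,
) -> MonopolarReview:
    """Monopolar review implied by per-contact latent qualities.

    The therapeutic-effect threshold falls and the side-effect threshold
    rises with quality; both carry Gaussian noise and review quantization.
    The chosen contact is the one with the widest true normalized window
    (ties resolved to the lowest contact index).
    """
    qualities = np.asarray(qualities, dtype=float)
    if qualities.size < 3:
        raise ValueError("need at least 3 contacts")
    rng = rng or np.random.default_rng(cfg.seed)
    ids = list(contact_ids) if contact_ids is not None else list(
        range(1, qualities.size + 1)
    )

    slope = 1.2 * cfg.quality_effect
    rows = []
    for cid, q in zip(ids, qualities):
        tet = 2.0 - slope * q + rng.normal(0.0, cfg.noise_sd)
        set_ = 3.5 + slope * q + rng.normal(0.0, cfg.noise_sd)
        tet_q = _quantize_threshold(tet, cfg)
        set_q = _quantize_threshold(set_, cfg)
        if rng.random() < cfg.missing_rate:
            tet_q = None
        if rng.random() < cfg.missing_rate:
            set_q = None
        rows.append(
            dict(contact_id=cid, set_ma=np.nan if set_q is None else set_q,
                 tet_ma=np.nan if tet_q is None else tet_q)
        )
    contacts = pd.DataFrame(rows)
    rev = MonopolarReview(
        patient_id=patient_id, side=side, contacts=contacts,
        amp_step=cfg.amp_step, amp_max=cfg.amp_max, amp_range=cfg.amp_range,
    )
    wt = window_table(rev)
    best = wt["norm_tw"].to_numpy()
    rev.chosen_contact = ids[int(np.argmax(best))]  # argmax: first max wins
    return rev


def _electrode_coordinates(
    n_contacts: int, side: str, rng: np.random.Generator
) -> np.ndarray:
    """Contacts on a line through a jittered center near the STN, 2 mm apart."""
    center = np.array([12.0, -13.0, -5.0]) + rng.normal(0.0, 1.0, 3)
    if side == "left":
        center[0] = -center[0]
    direction = np.array([0.3, 0.3, 0.9])
    direction /= np.linalg.norm(direction)
    offsets = (np.arange(n_contacts) - (n_contacts - 1) / 2.0) * 2.0
    return center[None, :] + offsets[:, None] * direction[None, :]


def _ring_levels(n_contacts: int) -> list:
    """Segment groups forming ring-mode composites (1-3-3-1 style leads)."""
    if n_contacts != 8:
        return []
    return [[2, 3, 4], [5, 6, 7]]


def planted_feature_names() -> list:
    """Feature columns carrying the latent quality signal, post-alignment."""
    # high-beta appears both via the oscillation amplitudes and via the
    # quality-weighted mixing of the shared high-beta source
    names = [f"stn_{b}" for b in ("low_beta", "high_beta", "high_gamma", "hfo")]
    for base, rel in COUPLED_PARCELS:
        hemi = "R" if rel == "I" else "L"  # after alignment, R = ipsilateral
        names.append(f"coh_{base}_{hemi}_high_beta")
    return names


def generate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Simulate a full cohort: signals, reviews, truth. Deterministic in seed."""
    from .connectivity import PARCELS  # local import to avoid cycle

    if cfg.n_parcels != len(PARCELS):
        raise ValueError(f"n_parcels must be {len(PARCELS)} for the parcel scheme")

    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    root = np.random.SeedSequence(cfg.seed)
    patient_seeds = root.spawn(cfg.n_patients)

    recordings, reviews, truth_rows = [], [], []
    for p in range(cfg.n_patients):
        pid = f"P{p:02d}"
        rng = np.random.default_rng(patient_seeds[p])

        parcel_sig = {
            label: cfg.background_sd * pink_noise(n, rng) for label in PARCELS
        }
        data, labels, roles, sides, contact_ids = [], [], [], [], []

        for side in ("left", "right"):
            ipsi, contra = ("L", "R") if side == "left" else ("R", "L")
            source = bandlimited_noise(n, cfg.fs, *COUPLING_BAND, rng)
            for base, rel in COUPLED_PARCELS:
                hemi = ipsi if rel == "I" else contra
                parcel_sig[f"{base}_{hemi}"] += cfg.parcel_coupling * source

            q = rng.standard_normal(cfg.contacts_per_electrode)
            coords = _electrode_coordinates(cfg.contacts_per_electrode, side, rng)
            for c in range(cfg.contacts_per_electrode):
                sig = cfg.background_sd * pink_noise(n, rng)
                for name, (lo, hi, amp, dep) in cfg.osc_amps.items():
                    a = amp
                    if dep:
                        a = amp * max(1.0 + cfg.quality_effect * q[c], 0.05)
                    sig += a * bandlimited_noise(n, cfg.fs, lo, hi, rng)
                w = cfg.coupling_weight * max(
                    1.0 + cfg.quality_effect * q[c], 0.0
                )
                sig += w * source
                sig += cfg.line_noise_amp * np.sin(
                    2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
                )
                data.append(sig)
                labels.append(f"stn_{side}_{c + 1}")
                roles.append("stn")
                sides.append(side)
                contact_ids.append(c + 1)

            contact_id_list = list(range(1, cfg.contacts_per_electrode + 1))
            q_all, ids_all, coords_all = list(q), list(contact_id_list), list(coords)
            if cfg.ring_mode:
                for group in _ring_levels(cfg.contacts_per_electrode):
                    seg_idx = [contact_id_list.index(g) for g in group]
                    ids_all.append("-".join(str(g) for g in group))
                    q_all.append(float(np.mean([q[i] for i in seg_idx])))
                    coords_all.append(np.mean([coords[i] for i in seg_idx], axis=0))
            review = generate_review(
                np.asarray(q_all), cfg, rng=rng, patient_id=pid, side=side,
                contact_ids=ids_all,
            )
            reviews.append(review)
            wt = window_table(review).set_index("contact_id")
            for cid, qv, xyz in zip(ids_all, q_all, coords_all):
                truth_rows.append(
                    dict(
                        patient_id=pid, side=side, contact_id=cid, q=qv,
                        x_mm=xyz[0], y_mm=xyz[1], z_mm=xyz[2],
                        norm_tw=wt.loc[cid, "norm_tw"],
                        chosen_flag=int(cid == review.chosen_contact),
                    )
                )

        for label in PARCELS:
            data.append(parcel_sig[label])
            labels.append(label)
            roles.append("parcel")
            sides.append(None)
            contact_ids.append(None)

        recordings.append(
            EpochedRecording(
                patient_id=pid, fs=cfg.fs, data=np.asarray(data),
                labels=labels, roles=roles, sides=sides, contact_ids=contact_ids,
            )
        )

    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(
        recordings=recordings, reviews=reviews, truth=truth,
        planted_features=planted_feature_names(), config=cfg,
    )


# ---------------------------------------------------------------------------
# on-disk interfaces


def save_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write signals to HDF5 and reviews/truth to CSV under ``out_dir``."""
    import h5py
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "signals.h5", "w") as h5:
        for rec in cohort.recordings:
            grp = h5.create_group(rec.patient_id)
            grp.attrs["fs"] = rec.fs
            for i, label in enumerate(rec.labels):
                ds = grp.create_dataset(label, data=rec.data[i])
                ds.attrs["role"] = rec.roles[i]
                ds.attrs["side"] = rec.sides[i] or ""
                ds.attrs["contact_id"] = (
                    -1 if rec.contact_ids[i] is None else rec.contact_ids[i]
                )

    rows = []
    for rev in cohort.reviews:
        for rec in rev.contacts.itertuples(index=False):
            rows.append(
                dict(
                    patient_id=rev.patient_id, side=rev.side,
                    contact_id=rec.contact_id, SET_mA=rec.set_ma,
                    TET_mA=rec.tet_ma, amp_step=rev.amp_step,
                    amp_max=rev.amp_max, amp_range=rev.amp_range,
                    chosen_flag=int(rec.contact_id == rev.chosen_contact),
                )
            )
    reviews_df = pd.DataFrame(rows).merge(
        cohort.truth[["patient_id", "side", "contact_id",
                      "x_mm", "y_mm", "z_mm"]],
        on=["patient_id", "side", "contact_id"], how="left",
    )
    reviews_df.to_csv(out / "reviews.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)


def load_reviews(path) -> list:
    """Rebuild MonopolarReview objects from a reviews CSV."""
    df = pd.read_csv(path)
    reviews = []
    for (pid, side), grp in df.groupby(["patient_id", "side"], sort=True):
        contacts = grp.rename(
            columns={"SET_mA": "set_ma", "TET_mA": "tet_ma"}
        )[["contact_id", "set_ma", "tet_ma"]].reset_index(drop=True)
        chosen = grp.loc[grp["chosen_flag"] == 1, "contact_id"]
        reviews.append(
            MonopolarReview(
                patient_id=pid, side=side, contacts=contacts,
                amp_step=float(grp["amp_step"].iloc[0]),
                amp_max=float(grp["amp_max"].iloc[0]),
                amp_range=float(grp["amp_range"].iloc[0]),
                chosen_contact=chosen.iloc[0] if len(chosen) else None,
            )
        )
    return reviews
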