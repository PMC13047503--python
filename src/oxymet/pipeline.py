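"""Per-animal and cohort-level analysis orchestration.

Ties the modules together: NIRS recording → pathlength + chromophore
fits + anoxia tHb calibration + StO₂; ASL stack → T1 map → ΔM → CBF →
ROI statistics; then the saturation partition / Fick oximetry and the
cohort statistics table.  Works on in-memory simulated objects or on an
on-disk dataset written by :func:`oxymet.synth.generate_cohort`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import asl as asl_mod
from . import nirs as nirs_mod
from . import oximetry as oxi_mod
from . import stats as stats_mod
from .optics import ExtinctionTable, load_extinction_table
from .synth import NirsRecording, SimulatedAsl, read_spectra_csv

log = logging.getLogger("oxymet")

__all__ = [
    "AnimalRecord",
    "analyze_nirs_recording",
    "analyze_asl",
    "oximetry_from_estimates",
    "analyze_dataset",
    "cohort_group_stats",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "animal_id", "group", "dHb_uM", "oxCCO_uM", "reCCO_uM", "totCCO_uM",
    "tHb_uM", "StO2_pct", "oxidized_fraction_pct", "pathlength_cm", "fit_rms",
    "CBF_mean", "CBF_sd", "n_voxels", "rater_flag",
    "SaO2_pct", "SvO2_pct", "OEF", "CMRO2_mlO2_100g_min", "hypoxic_flag",
]


@dataclass
class AnimalRecord:
    """One analyzed animal: chromophores + perfusion + oximetry."""

    animal_id: str
    group: str
    chromophores: nirs_mod.ChromophoreEstimates
    perfusion: asl_mod.PerfusionResult
    oximetry: oxi_mod.OximetryResult

    def to_row(self) -> dict:
        c, p, o = self.chromophores, self.perfusion, self.oximetry
        return {
            "animal_id": self.animal_id,
            "group": self.group,
            "dHb_uM": c.dHb,
            "oxCCO_uM": c.oxCCO,
            "reCCO_uM": c.reCCO,
            "totCCO_uM": c.totCCO,
            "tHb_uM": c.tHb,
            "StO2_pct": c.StO2,
            "oxidized_fraction_pct": 100.0 * c.oxidized_fraction,
            "pathlength_cm": c.pathlength_hat,
            "fit_rms": c.fit_residual,
            "CBF_mean": p.roi_mean,
            "CBF_sd": p.roi_sd,
            "n_voxels": p.n_voxels,
            "rater_flag": False,
            "SaO2_pct": o.SaO2,
            "SvO2_pct": o.SvO2,
            "OEF": o.OEF,
            "CMRO2_mlO2_100g_min": o.CMRO2,
            "hypoxic_flag": False,
        }


def analyze_nirs_recording(
    times: np.ndarray,
    wavelengths: np.ndarray,
    attenuation: np.ndarray,
    table: ExtinctionTable,
    protocol: nirs_mod.NirsProtocol,
    water_fraction: float = 0.80,
    windows: Mapping[str, tuple[float, float]] | None = None,
    smoothing: tuple[int, int] = (11, 3),
) -> nirs_mod.ChromophoreEstimates:
    """Full NIRS inversion of one recording.

    The mean spectrum over the ASL-aligned averaging window yields the
    pathlength; frame-wise chromophore fits inside that window are then
    averaged for the baseline concentrations; the dHb trace inside the
    anoxia window calibrates tHb; StO₂ follows from the baseline dHb
    mean and the calibrated tHb.
    """
    table = table.resample(wavelengths)
    lo_avg, hi_avg = protocol.averaging_window
    avg_sel = (times >= lo_avg) & (times < hi_avg)  # half-open [start, end)
    if not np.any(avg_sel):
        raise nirs_mod.WindowError("no frames inside the averaging window")
    mean_spec = attenuation[avg_sel].mean(axis=0)
    from .optics import AttenuationSpectrum

    L_hat = nirs_mod.estimate_pathlength(
        AttenuationSpectrum(wavelengths, mean_spec), table,
        water_fraction=water_fraction, smoothing=smoothing,
    )
    fit_base = nirs_mod.fit_chromophores(
        attenuation[avg_sel], L_hat, table,
        windows=windows, water_fraction=water_fraction, smoothing=smoothing,
    )
    avg = nirs_mod.average_over_window(
        times[avg_sel],
        {"dHb": fit_base.dHb, "oxCCO": fit_base.oxCCO, "reCCO": fit_base.reCCO},
        protocol.averaging_window,
    )

    if protocol.anoxia_window is not None:
        lo, hi = protocol.anoxia_window
        anox_sel = (times >= lo) & (times < hi)
        if not np.any(anox_sel):
            raise nirs_mod.WindowError("recording does not cover the anoxia window")
        fit_anox = nirs_mod.fit_chromophores(
            attenuation[anox_sel], L_hat, table,
            windows=windows, water_fraction=water_fraction, smoothing=smoothing,
        )
        thb = nirs_mod.estimate_tHb_anoxia(
            times[anox_sel], np.atleast_1d(fit_anox.dHb), protocol
        ).tHb
    else:
        raise nirs_mod.WindowError(
            "protocol has no anoxia window; supply tHb externally"
        )
    sto2 = nirs_mod.compute_StO2(avg.dHb, thb)
    return nirs_mod.ChromophoreEstimates(
        dHb=avg.dHb,
        oxCCO=avg.oxCCO,
        reCCO=avg.reCCO,
        tHb=thb,
        StO2=sto2.value,
        pathlength_hat=L_hat,
        fit_residual=float(np.mean(np.atleast_1d(fit_base.fit_rms))),
        StO2_clipped=sto2.clipped,
    )


def analyze_recording_object(rec: NirsRecording, table, **kw) -> nirs_mod.ChromophoreEstimates:
    return analyze_nirs_recording(
        rec.times, rec.wavelengths, rec.attenuation, table, rec.protocol, **kw
    )


def analyze_asl(
    stack: asl_mod.AslStack,
    roi_mask: np.ndarray,
    params: asl_mod.AslModelParams | None = None,
) -> asl_mod.PerfusionResult:
    """T1 map → MT-corrected ΔM → CBF map → ROI statistics."""
    params = params or asl_mod.AslModelParams()
    t1_map, m0_map = asl_mod.fit_t1_map(stack.tr_series, stack.tr_list)
    dm, mctrl = asl_mod.perfusion_weighted(stack.controls, stack.tags)
    # background voxels routinely trip the non-positive-control warning;
    # record it in the run log rather than spamming the console
    import warnings

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cbf = asl_mod.quantify_cbf(dm, mctrl, t1_map, params)
    for w in caught:
        log.debug("quantify_cbf: %s", w.message)
    mean, sd, n = asl_mod.roi_statistics(cbf, roi_mask)
    return asl_mod.PerfusionResult(
        t1_map=t1_map, m0_map=m0_map, dM_map=dm, cbf_map=cbf,
        roi_mean=mean, roi_sd=sd, n_voxels=n, mask=np.asarray(roi_mask, dtype=bool),
    )


def analyze_simulated_asl(sim: SimulatedAsl, params=None) -> asl_mod.PerfusionResult:
    return analyze_asl(sim.stack, sim.cortex_mask, params)


def oximetry_from_estimates(
    sto2: float,
    cbf: float,
    sao2: float,
    params: oxi_mod.OximetryParams | None = None,
) -> oxi_mod.OximetryResult:
    """SvO₂ → OEF → CMRO₂ chain from recovered StO₂ and CBF.

    A raw extraction fraction outside [0, 1] (tissue saturation above
    the arterial value, or below the fully-extracted limit) is clamped
    and flagged rather than dropped.
    """
    params = params or oxi_mod.OximetryParams()
    svo2 = oxi_mod.compute_SvO2(sto2, sao2, params)
    oef_raw = oxi_mod.compute_OEF(sao2, svo2.value)
    oef = float(np.clip(oef_raw, 0.0, 1.0))
    cmro2 = oxi_mod.compute_CMRO2(max(cbf, 0.0), oef, sao2, params)
    return oxi_mod.OximetryResult(
        SaO2=sao2, SvO2=svo2.value, OEF=oef, CMRO2=cmro2,
        SvO2_flagged=svo2.flagged, OEF_clamped=oef != oef_raw,
    )


def analyze_dataset(
    dataset_dir,
    table: ExtinctionTable | None = None,
    oxi_params: oxi_mod.OximetryParams | None = None,
    asl_params: asl_mod.AslModelParams | None = None,
) -> pd.DataFrame:
    """Analyze an on-disk dataset written by :func:`generate_cohort`.

    Missing or unreadable animals are logged and excluded; the run
    continues.  Hypoxia flags are assigned against the naive group's
    recovered StO₂ reference when a naive arm is present.
    """
    import nibabel as nib

    root = Path(dataset_dir)
    if not root.exists() or not (root / "manifest.csv").exists():
        raise FileNotFoundError(f"{root} is not a generated dataset (no manifest.csv)")
    manifest = pd.read_csv(root / "manifest.csv")
    table = table or load_extinction_table()
    rows = []
    excluded = []
    for _, mrow in manifest.iterrows():
        adir = root / str(mrow["group"]) / str(mrow["animal_id"])
        try:
            times, wavelengths, atten = read_spectra_csv(adir / "spectra.csv")
            sidecar = json.loads((adir / "sidecar.json").read_text())
            protocol = nirs_mod.NirsProtocol(
                sampling_rate=float(sidecar["sampling_rate_hz"]),
                total_duration=float(times[-1]) + 1.0,
                anoxia_window=tuple(sidecar["anoxia_window_s"]) or None,
                averaging_window=tuple(sidecar["averaging_window_s"]),
            )
            chrom = analyze_nirs_recording(times, wavelengths, atten, table, protocol)

            def load(name):
                img = np.asarray(
                    nib.load(str(adir / "asl" / f"{name}.nii.gz")).dataobj, dtype=float
                )
                return np.moveaxis(img, -1, 0) if img.ndim == 3 else img

            stack = asl_mod.AslStack(
                load("controls"), load("tags"), load("tr_series"),
                tuple(t / 1000.0 for t in sidecar["tr_list_ms"]),
            )
            mask = np.asarray(
                nib.load(str(adir / "asl" / "cortex_mask.nii.gz")).dataobj
            ).astype(bool)
            perf = analyze_asl(stack, mask, asl_params)
            oxi = oximetry_from_estimates(
                chrom.StO2, perf.roi_mean, float(sidecar["sao2_pct"]), oxi_params
            )
            rows.append(
                AnimalRecord(str(mrow["animal_id"]), str(mrow["group"]), chrom, perf, oxi).to_row()
            )
        except (OSError, ValueError, KeyError) as exc:
            excluded.append((str(mrow["animal_id"]), repr(exc)))
            log.warning("excluding %s: %s", mrow["animal_id"], exc)
    if not rows:
        raise ValueError("no analyzable animals in the dataset")
    df = pd.DataFrame(rows)
    if "naive" in set(df["group"]):
        ref = df.loc[df["group"] == "naive", "StO2_pct"]
        if ref.size >= 2 and ref.std(ddof=1) > 0:
            res = oxi_mod.classify_hypoxia(
                df["StO2_pct"].to_numpy(), float(ref.mean()), float(ref.std(ddof=1))
            )
            df["hypoxic_flag"] = res.flags
    df.attrs["excluded"] = excluded
    return df[COHORT_COLUMNS]


def cohort_group_stats(df: pd.DataFrame, metrics=None) -> dict:
    """Per-metric group summaries + Kruskal–Wallis pairwise comparisons."""
    metrics = metrics or ["CBF_mean", "StO2_pct", "OEF", "CMRO2_mlO2_100g_min",
                          "totCCO_uM", "oxidized_fraction_pct"]
    report = {}
    for metric in metrics:
        groups = {
            g: sub[metric].dropna().to_numpy() for g, sub in df.groupby("group")
        }
        groups = {g: v for g, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            continue
        comp = stats_mod.kruskal_wallis_pairwise(groups)
        report[metric] = {
            "H": comp.statistic,
            "omnibus_p": comp.omnibus_p,
            "pairwise": [
                {"pair": list(p.pair), "raw_p": p.raw_p, "bonferroni_p": p.bonferroni_p}
                for p in comp.pairwise
            ],
            "groups": [s._asdict() for s in comp.summaries],
        }
    return report


def group_summary_frame(report: dict) -> pd.DataFrame:
    """Flatten a :func:`cohort_group_stats` report into a figure-ready table."""
    rows = []
    for metric, entry in report.items():
        for g in entry["groups"]:
            rows.append({"metric": metric, **g, "omnibus_p": entry["omnibus_p"]})
    return pd.DataFrame(rows)
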