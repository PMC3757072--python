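"""Virtual electrophysiology protocols.

A :class:`VirtualPhysiology` session holds a dictionary, the (single,
global) LCA parameter set and the whitening filter, and exposes one method
per protocol: optimal-grating search, end-stopping (bar length sweep), size
tuning across contrasts, orientation tuning across contrasts, center–
surround orientation tuning, center/surround contrast response, and
cross-orientation (plaid) suppression.  Every protocol is a deterministic
function of the dictionary, the parameters, and the printed stimulus grids;
responses to drifting gratings are measured over one full temporal cycle by
the mean rate or the F1 amplitude, static responses by the converged steady
state.  :meth:`run_population` applies the full battery to a list of units
and assembles the population metrics table.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .lca import (
    LCAParams,
    lca_encode_batch,
    lca_encode_movie_batch,
)
from .metrics import TuningCurve
from .stimuli import StimulusSpec, prepare, drift
from .whitening import WhiteningFilter, build_whitening_filter

__all__ = ["OptimalStimulus", "VirtualPhysiology", "SEARCH_GRID"]

log = logging.getLogger(__name__)

#: exhaustive search grid of the optimal-grating protocol
SEARCH_GRID = {
    "size": np.arange(1.0, 16.0 + 0.25, 0.5),
    "orientation": np.arange(0.0, 180.0, 5.0),
    "spatial_freq": np.arange(0.5, 2.0 + 0.125, 0.25),
    "phase": np.arange(0.0, 2 * math.pi - 1e-9, math.pi / 4),
}

SIZE_TUNING_CONTRASTS = (0.05, 0.15, 0.25, 0.35, 0.45, 0.5)
ORIENTATION_CONTRASTS = (0.1, 0.2, 0.3, 0.4, 0.5)
LOG_CONTRASTS = (0.0, 0.03, 0.06, 0.12, 0.25, 0.5)
HIGH_CONTRAST = 0.5
LOW_CONTRAST = 0.05


@dataclass
class OptimalStimulus:
    """Winning circular grating of the exhaustive search for one unit."""

    unit: int
    center: tuple[float, float]
    size: float
    orientation: float
    spatial_freq: float
    phase: float
    response: float

    @property
    def responsive(self) -> bool:
        return self.response > 0

    def spec(self, contrast: float, **overrides) -> StimulusSpec:
        kw = dict(
            kind="grating_disc",
            center=self.center,
            size=self.size,
            orientation=self.orientation,
            spatial_freq=self.spatial_freq,
            phase=self.phase,
            contrast=contrast,
        )
        kw.update(overrides)
        return StimulusSpec(**kw)


class VirtualPhysiology:
    """One recording session on a fixed dictionary and parameter set."""

    def __init__(
        self,
        dictionary,
        params: LCAParams | None = None,
        whitener: WhiteningFilter | None = None,
        temporal_freq: float = 3.0,
        frame_rate: float = 30.0,
        static_tol: float | None = None,
        search_mode: str = "two_step",
    ):
        self.dictionary = dictionary
        self.params = params or LCAParams()
        self.whitener = whitener or build_whitening_filter(dictionary.patch_side)
        if self.whitener.side != dictionary.patch_side:
            raise ValueError("whitening filter grid does not match the patch side")
        self.temporal_freq = temporal_freq
        self.frame_rate = frame_rate
        self.static_tol = static_tol
        if search_mode not in ("two_step", "brute_force"):
            raise ValueError(f"unknown search mode {search_mode!r}")
        self.search_mode = search_mode
        self._optima: dict[int, OptimalStimulus] = {}
        self._frame_cache: dict = {}

    # ------------------------------------------------------------- plumbing
    @property
    def cycle_frames(self) -> int:
        return int(round(self.frame_rate / self.temporal_freq))

    @property
    def cycle_steps(self) -> int:
        return self.cycle_frames * self.params.steps_per_frame

    def unit_center(self, unit: int) -> tuple[float, float]:
        row = self.dictionary.meta.iloc[unit]
        return (float(row["center_row"]), float(row["center_col"]))

    def static_responses(self, specs: list[StimulusSpec], unit: int) -> np.ndarray:
        """Steady-state rate of ``unit`` for each static stimulus.

        Runs the full ``static_steps`` Euler integration per stimulus
        (batched, single precision: rate error ~1e-5, negligible against the
        grid spacing of every sweep).
        """
        X = np.stack([prepare(s, self.whitener).reshape(-1) for s in specs], axis=1)
        A = lca_encode_batch(
            self.dictionary, X, self.params, tol=self.static_tol, dtype=np.float32
        )
        return A[unit].astype(float)

    def _drift_frames(self, spec: StimulusSpec, n_cycles: float = 1.0) -> np.ndarray:
        key = (spec, n_cycles, self.temporal_freq, self.frame_rate)
        if key not in self._frame_cache:
            seq = drift(
                spec,
                temporal_freq=self.temporal_freq,
                frame_rate=self.frame_rate,
                n_cycles=n_cycles,
                whitener=self.whitener,
            )
            self._frame_cache[key] = seq.frames
        return self._frame_cache[key]

    def drifting_responses(
        self, specs: list[StimulusSpec], unit: int, statistic: str = "f1"
    ) -> np.ndarray:
        """Response of ``unit`` to one drift cycle of each stimulus.

        ``statistic`` is ``"f1"`` (amplitude at the drift frequency) or
        ``"mean"``; each condition starts from the zero network state.
        """
        stack = np.stack([self._drift_frames(s) for s in specs])
        traj = lca_encode_movie_batch(self.dictionary, stack, self.params)
        traces = traj[:, :, unit]
        if statistic == "f1":
            return np.array([metrics.f1(t, self.cycle_steps) for t in traces])
        if statistic == "mean":
            return traces.mean(axis=1)
        raise ValueError(f"unknown statistic {statistic!r}")

    # ------------------------------------------------------- optimal search
    def find_optimal_grating(self, unit: int, contrast: float | None = None):
        """Exhaustive search for the static circular grating maximizing the
        unit's steady-state rate (size 1–16 px step 0.5, orientation 0–175°
        step 5°, SF 0.5–2 rad/px step 0.25, phase 0–2π step π/4).

        The two-step mode first sweeps (orientation, SF, phase) at the
        size-grid midpoint, then re-sweeps all four axes with
        orientation/SF restricted to a one-step neighborhood of the coarse
        winner; ``search_mode="brute_force"`` sweeps the full grid in one
        pass.  Ties break to the first candidate in lexicographic
        (size, orientation, SF, phase) order.  A unit with zero response
        everywhere is flagged (``response == 0``) and excluded downstream.
        """
        if unit in self._optima:
            return self._optima[unit]
        contrast = 0.3 if contrast is None else contrast
        center = self.unit_center(unit)
        g = SEARCH_GRID

        def spec_for(size, ori, sf, ph):
            return StimulusSpec(
                kind="grating_disc", center=center, size=size,
                orientation=ori, spatial_freq=sf, phase=ph, contrast=contrast,
            )

        if self.search_mode == "brute_force":
            combos = [
                (s, o, f, p)
                for s in g["size"]
                for o in g["orientation"]
                for f in g["spatial_freq"]
                for p in g["phase"]
            ]
        else:
            mid_size = g["size"][len(g["size"]) // 2]
            coarse_phases = g["phase"][::2]  # quarter-cycle steps suffice here
            coarse = [
                (mid_size, o, f, p)
                for o in g["orientation"]
                for f in g["spatial_freq"]
                for p in coarse_phases
            ]
            r = self.static_responses([spec_for(*c) for c in coarse], unit)
            _, o_best, f_best, _ = coarse[int(np.argmax(r))]
            oi = list(g["orientation"]).index(o_best)
            fi = list(g["spatial_freq"]).index(f_best)
            oris = [g["orientation"][i % len(g["orientation"])] for i in (oi - 1, oi, oi + 1)]
            sfs = [g["spatial_freq"][i] for i in (fi - 1, fi, fi + 1) if 0 <= i < len(g["spatial_freq"])]
            combos = sorted(
                {
                    (s, o, f, p)
                    for s in g["size"]
                    for o in oris
                    for f in sfs
                    for p in g["phase"]
                }
            )
        r = self.static_responses([spec_for(*c) for c in combos], unit)
        best = int(np.argmax(r))
        size, ori, sf, ph = combos[best]
        opt = OptimalStimulus(
            unit=unit, center=center, size=float(size), orientation=float(ori),
            spatial_freq=float(sf), phase=float(ph), response=float(r[best]),
        )
        if not opt.responsive:
            log.warning("unit %d unresponsive over the full search grid", unit)
        self._optima[unit] = opt
        return opt

    # ----------------------------------------------------------- protocols
    def end_stopping(
        self, unit: int, lengths=None, contrast: float = 0.3, polarity: int = 1
    ) -> TuningCurve:
        """Bar length sweep: optimal bar (width 2, optimal orientation,
        location optimized over a 5-pixel neighborhood of the grating
        center), then length 1–16 px, static steady-state rate."""
        opt = self.find_optimal_grating(unit)
        lengths = np.arange(1.0, 17.0) if lengths is None else np.asarray(lengths)

        def bar(center, length):
            return StimulusSpec(
                kind="bar", center=center, size=float(length), width=2.0,
                orientation=opt.orientation, contrast=contrast, polarity=polarity,
            )

        offsets = [
            (opt.center[0] + dr, opt.center[1] + dc)
            for dr in range(-2, 3)
            for dc in range(-2, 3)
        ]
        r = self.static_responses([bar(c, opt.size) for c in offsets], unit)
        best_center = offsets[int(np.argmax(r))]
        responses = self.static_responses(
            [bar(best_center, L) for L in lengths], unit
        )
        return TuningCurve(
            "length", lengths, responses, statistic="steady_state",
            condition={"contrast": contrast, "center": best_center},
        )

    def size_tuning(
        self, unit: int, contrasts=SIZE_TUNING_CONTRASTS, sizes=None
    ) -> dict[float, TuningCurve]:
        """Drifting-disc size sweep (1–16 px step 1) at each contrast; F1."""
        opt = self.find_optimal_grating(unit)
        sizes = np.arange(1.0, 17.0) if sizes is None else np.asarray(sizes)
        out = {}
        for c in contrasts:
            specs = [opt.spec(c, size=float(s)) for s in sizes]
            resp = self.drifting_responses(specs, unit, statistic="f1")
            out[c] = TuningCurve(
                "size", sizes, resp, statistic="f1", condition={"contrast": c}
            )
        return out

    def orientation_tuning(
        self, unit: int, contrasts=ORIENTATION_CONTRASTS, orientations=None
    ) -> dict[float, TuningCurve]:
        """Drifting optimal-size disc, orientation 0–180° step 5°; mean rate."""
        opt = self.find_optimal_grating(unit)
        orientations = (
            np.arange(0.0, 180.0 + 2.5, 5.0) if orientations is None
            else np.asarray(orientations)
        )
        out = {}
        for c in contrasts:
            specs = [opt.spec(c, orientation=float(o % 180.0)) for o in orientations]
            resp = self.drifting_responses(specs, unit, statistic="mean")
            out[c] = TuningCurve(
                "orientation", orientations, resp, statistic="mean",
                condition={"contrast": c},
            )
        return out

    def surround_orientation_tuning(
        self,
        unit: int,
        center_radius_offset: float = 0.0,
        gap: float = 0.0,
        center_contrast: float = 0.3,
        surround_contrast: float = 0.3,
        surround_orientations=None,
    ) -> tuple[TuningCurve, TuningCurve]:
        """Center–surround protocol: center disc fixed at the optimal
        orientation, 2-px-thick phase-locked annulus at swept orientation.

        Returns ``(center orientation tuning, center+surround response vs
        surround orientation)``, both mean-rate curves.  The annulus inner
        radius is the center radius plus ``gap``; an annulus pushed entirely
        off-patch leaves the center-alone response.
        """
        opt = self.find_optimal_grating(unit)
        radius = opt.size / 2.0 + center_radius_offset
        surround_orientations = (
            SEARCH_GRID["orientation"] if surround_orientations is None
            else np.asarray(surround_orientations)
        )
        center_spec = opt.spec(center_contrast, size=2 * radius)
        # center-alone orientation tuning (dashed curve of the physiology plot)
        center_specs = [
            center_spec.replace(orientation=float(o)) for o in surround_orientations
        ]
        center_resp = self.drifting_responses(center_specs, unit, statistic="mean")
        center_curve = TuningCurve(
            "orientation", surround_orientations, center_resp, statistic="mean",
            condition={"contrast": center_contrast, "component": "center_alone"},
        )

        def with_surround(ori):
            annulus = StimulusSpec(
                kind="grating_annulus", center=opt.center, inner_radius=radius,
                gap=gap, width=2.0, orientation=float(ori),
                spatial_freq=opt.spatial_freq, phase=opt.phase,
                contrast=surround_contrast,
            )
            return center_spec.replace(kind="plaid", mask=annulus)

        sur_specs = [with_surround(o) for o in surround_orientations]
        sur_resp = self.drifting_responses(sur_specs, unit, statistic="mean")
        surround_curve = TuningCurve(
            "surround_orientation", surround_orientations, sur_resp,
            statistic="mean",
            condition={
                "center_contrast": center_contrast,
                "surround_contrast": surround_contrast,
                "gap": gap,
                "center_radius_offset": center_radius_offset,
            },
        )
        return center_curve, surround_curve

    def contrast_response(
        self,
        unit: int,
        mode: str = "center_contrast_sweep",
        surround_kind: str = "none",
        contrasts=LOG_CONTRASTS,
        fixed_contrast: float | None = None,
    ) -> TuningCurve:
        """Contrast sweeps with a fixed surround (F1 statistic).

        ``center_contrast_sweep``: center contrast takes the logarithmic
        values (0, 0.03, 0.06, 0.12, 0.25, 0.5) with the surround contrast
        held at 0.5.  ``surround_contrast_sweep``: surround contrast sweeps
        the same values with the center held at its default contrast.
        ``surround_kind`` is none | iso | ortho | uniform.
        """
        opt = self.find_optimal_grating(unit)
        radius = opt.size / 2.0
        if mode not in ("center_contrast_sweep", "surround_contrast_sweep"):
            raise ValueError(f"unknown mode {mode!r}")
        if surround_kind not in ("none", "iso", "ortho", "uniform"):
            raise ValueError(f"unknown surround kind {surround_kind!r}")

        def annulus(ori, contrast):
            return StimulusSpec(
                kind="grating_annulus", center=opt.center, inner_radius=radius,
                width=2.0, orientation=ori, spatial_freq=opt.spatial_freq,
                phase=opt.phase, contrast=contrast,
            )

        def stimulus(center_c, surround_c):
            center = opt.spec(center_c)
            if surround_kind == "none" or surround_c == 0:
                return center
            if surround_kind == "uniform":
                ring = annulus(opt.orientation, surround_c).replace(spatial_freq=0.0)
            else:
                ori = opt.orientation if surround_kind == "iso" else (
                    (opt.orientation + 90.0) % 180.0
                )
                ring = annulus(ori, surround_c)
            return center.replace(kind="plaid", mask=ring)

        if mode == "center_contrast_sweep":
            fixed = 0.5 if fixed_contrast is None else fixed_contrast
            specs = [stimulus(c, fixed) for c in contrasts]
            name = "center_contrast"
        else:
            fixed = 0.3 if fixed_contrast is None else fixed_contrast
            specs = [stimulus(fixed, c) for c in contrasts]
            name = "surround_contrast"
        resp = self.drifting_responses(specs, unit, statistic="f1")
        return TuningCurve(
            name, np.asarray(contrasts), resp, statistic="f1",
            condition={"surround_kind": surround_kind, "fixed_contrast": fixed},
        )

    def cross_orientation(
        self,
        unit: int,
        mask_orientations=None,
        test_contrast: float = 0.3,
        mask_contrast: float = 0.3,
    ) -> TuningCurve:
        """Plaid protocol: test grating at the optimum plus a superimposed
        mask at swept orientation, both drifting phase-locked; F1 at the
        test temporal frequency.  A zero-contrast mask reproduces the
        test-alone response exactly."""
        opt = self.find_optimal_grating(unit)
        mask_orientations = (
            SEARCH_GRID["orientation"] if mask_orientations is None
            else np.asarray(mask_orientations)
        )
        test = opt.spec(test_contrast)

        def plaid(mask_ori):
            if mask_contrast == 0:
                return test
            mask = opt.spec(mask_contrast, orientation=float(mask_ori % 180.0))
            return test.replace(kind="plaid", mask=mask)

        specs = [plaid(o) for o in mask_orientations]
        resp = self.drifting_responses(specs, unit, statistic="f1")
        return TuningCurve(
            "mask_orientation", mask_orientations, resp, statistic="f1",
            condition={"test_contrast": test_contrast, "mask_contrast": mask_contrast},
        )

    def plaid_vs_test(
        self, unit: int, test_contrast: float, mask_contrast: float | None = None
    ) -> tuple[float, float]:
        """(test-alone F1, plaid F1 with an ortho mask) at one test contrast."""
        opt = self.find_optimal_grating(unit)
        mc = test_contrast if mask_contrast is None else mask_contrast
        test = opt.spec(test_contrast)
        mask = opt.spec(mc, orientation=(opt.orientation + 90.0) % 180.0)
        plaid = test.replace(kind="plaid", mask=mask)
        r = self.drifting_responses([test, plaid], unit, statistic="f1")
        return float(r[0]), float(r[1])

    # ----------------------------------------------------------- population
    def run_population(
        self,
        units,
        contrasts_high_low: tuple[float, float] = (HIGH_CONTRAST, LOW_CONTRAST),
        cross_test_contrasts: tuple[float, float] = (0.5, 0.1),
        facilitation_offset: float = 0.0,
        checkpoint_dir: str | Path | None = None,
    ) -> pd.DataFrame:
        """Apply the full battery to every unit and tabulate the metrics.

        Per unit: optimal grating (CRF size), size tuning -> SI at high/low
        contrast, ΔSI, peak sizes and expansion ratio; orientation tuning ->
        half-width per contrast and half-width-vs-contrast slope (Gaussian
        fit failures recorded as exclusions, not errors); surround tuning ->
        facilitation ratio at high/low contrast; plaid -> cross-orientation
        ratio at high/low test contrast.  Unresponsive units are flagged and
        skipped.  With ``checkpoint_dir`` set, completed per-unit rows are
        written as JSON and re-runs resume from them.
        """
        high, low = contrasts_high_low
        ckpt = Path(checkpoint_dir) if checkpoint_dir else None
        if ckpt:
            ckpt.mkdir(parents=True, exist_ok=True)
        rows = []
        for unit in units:
            if ckpt and (ckpt / f"unit_{unit}.json").exists():
                rows.append(json.loads((ckpt / f"unit_{unit}.json").read_text()))
                continue
            row = self._population_row(
                int(unit), high, low, cross_test_contrasts, facilitation_offset
            )
            rows.append(row)
            if ckpt:
                (ckpt / f"unit_{unit}.json").write_text(json.dumps(row))
        return pd.DataFrame(rows)

    def _population_row(self, unit, high, low, cross_tcs, fac_offset) -> dict:
        log.info("population battery: unit %d", unit)
        row: dict = {"unit": unit, "excluded": False, "exclusion_reason": ""}
        opt = self.find_optimal_grating(unit)
        row.update(
            crf_size=opt.size, opt_orientation=opt.orientation,
            opt_spatial_freq=opt.spatial_freq, opt_phase=opt.phase,
            opt_response=opt.response,
        )
        if not opt.responsive:
            row.update(excluded=True, exclusion_reason="unresponsive")
            return row

        # --- size tuning: SI, peak sizes, expansion ratio
        size_curves = self.size_tuning(unit, contrasts=(low, high))
        for label, c in (("low", low), ("high", high)):
            curve = size_curves[c]
            try:
                row[f"si_{label}"] = metrics.suppression_index(curve)
                row[f"peak_size_{label}"] = curve.peak_abscissa
            except ValueError:
                row[f"si_{label}"] = np.nan
                row[f"peak_size_{label}"] = np.nan
        if np.isfinite(row.get("si_low", np.nan)) and np.isfinite(
            row.get("si_high", np.nan)
        ):
            row["delta_si"] = metrics.delta_si(row["si_low"], row["si_high"])
            row["expansion_ratio"] = metrics.expansion_ratio(
                row["peak_size_low"], row["peak_size_high"]
            )
        else:
            row["delta_si"] = np.nan
            row["expansion_ratio"] = np.nan

        # --- orientation tuning: half-widths and slope
        ori_curves = self.orientation_tuning(unit)
        hws, cs = [], []
        for c, curve in ori_curves.items():
            try:
                hws.append(metrics.orientation_halfwidth(curve))
                cs.append(c)
            except (RuntimeError, ValueError):
                pass
            row[f"halfwidth_c{c:g}"] = hws[-1] if cs and cs[-1] == c else np.nan
        if len(hws) >= 2:
            row["halfwidth_slope"] = metrics.halfwidth_slope(hws, cs)
            row["halfwidth_high"] = hws[-1]
        else:
            row["halfwidth_slope"] = np.nan
            row["halfwidth_high"] = np.nan
            row["excluded"] = True
            row["exclusion_reason"] = "orientation fit failure"

        # --- surround facilitation at high and low contrast
        for label, c in (("high", high), ("low", low)):
            center_curve, surround_curve = self.surround_orientation_tuning(
                unit, center_radius_offset=fac_offset,
                center_contrast=c, surround_contrast=c,
            )
            center_opt = float(np.max(center_curve.responses))
            try:
                row[f"facilitation_{label}"] = metrics.facilitation_ratio(
                    surround_curve, center_opt
                )
            except ValueError:
                row[f"facilitation_{label}"] = np.nan

        # --- cross-orientation suppression ratio at high and low test contrast
        for label, tc in (("high", cross_tcs[0]), ("low", cross_tcs[1])):
            test_r, plaid_r = self.plaid_vs_test(unit, tc)
            try:
                row[f"cross_ratio_{label}"] = metrics.cross_orientation_ratio(
                    test_r, plaid_r
                )
            except ValueError:
                row[f"cross_ratio_{label}"] = np.nan
        return row
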