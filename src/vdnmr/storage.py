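"""HDF5 batch container for synthetic training sets.

Layout (one group ``set_%06d`` per training set):

* ``input_nocoup``, ``input_coup``, ``target`` -- complex datasets of
  shape (2, n_h, n_c): cos-/sin-modulated t1 interferograms, complex in
  the 1H quadrature;
* ``systems`` -- float dataset (n_peaks, 15), one row per cross-peak in
  the field order of :class:`vdnmr.simulate.AromaticSpinSystem`;
* group attrs -- acquisition scheme (sw_h, sw_c, n_c, n_h, tau_coup),
  solvent draw (amp, slp, inverted), seed, noise_sd and the per-plane
  phase-error draws (JSON).
"""

from __future__ import annotations

import json
from dataclasses import fields as dc_fields

import h5py
import numpy as np

from .simulate import (
    AcquisitionScheme,
    AromaticSpinSystem,
    SolventArtifact,
    SyntheticSpectrumSet,
)

__all__ = ["save_batch", "load_batch"]

_SYS_FIELDS = [f.name for f in dc_fields(AromaticSpinSystem)]


def save_batch(sets, path):
    with h5py.File(path, "w") as fh:
        fh.attrs["n_sets"] = len(sets)
        fh.attrs["system_fields"] = json.dumps(_SYS_FIELDS)
        for i, ss in enumerate(sets):
            g = fh.create_group(f"set_{i:06d}")
            for name in ("input_nocoup", "input_coup", "target"):
                g.create_dataset(name, data=getattr(ss, name))
            rows = np.array([[getattr(s, f) for f in _SYS_FIELDS] for s in ss.systems])
            g.create_dataset("systems", data=rows)
            acq = ss.acq
            g.attrs.update(
                {
                    "sw_h": acq.sw_h,
                    "sw_c": acq.sw_c,
                    "n_c": acq.n_c,
                    "n_h": acq.n_h,
                    "tau_coup": acq.tau_coup,
                    "solvent_amp": ss.solvent.amp,
                    "solvent_slp": ss.solvent.slp,
                    "solvent_inverted": ss.solvent.inverted,
                    "seed": ss.seed,
                    "noise_sd": ss.noise_sd,
                    "phase_errors": json.dumps(ss.phase_errors),
                }
            )


def load_batch(path):
    out = []
    with h5py.File(path, "r") as fh:
        n = int(fh.attrs["n_sets"])
        for i in range(n):
            g = fh[f"set_{i:06d}"]
            systems = [
                AromaticSpinSystem(**dict(zip(_SYS_FIELDS, row)))
                for row in np.asarray(g["systems"])
            ]
            acq = AcquisitionScheme(
                sw_h=float(g.attrs["sw_h"]),
                sw_c=float(g.attrs["sw_c"]),
                n_c=int(g.attrs["n_c"]),
                n_h=int(g.attrs["n_h"]),
                tau_coup=float(g.attrs["tau_coup"]),
            )
            out.append(
                SyntheticSpectrumSet(
                    input_nocoup=np.asarray(g["input_nocoup"]),
                    input_coup=np.asarray(g["input_coup"]),
                    target=np.asarray(g["target"]),
                    systems=systems,
                    solvent=SolventArtifact(
                        amp=float(g.attrs["solvent_amp"]),
                        slp=float(g.attrs["solvent_slp"]),
                        inverted=bool(g.attrs["solvent_inverted"]),
                    ),
                    acq=acq,
                    seed=int(g.attrs["seed"]),
                    noise_sd=float(g.attrs["noise_sd"]),
                    phase_errors=json.loads(g.attrs["phase_errors"]),
                )
            )
    return out
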