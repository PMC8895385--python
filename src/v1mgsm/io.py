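"""State serialization and run configuration.

States are stored as NumPy ``.npz`` containers (endianness-safe) holding the
priors, the trace-normalised covariance of every component together with its
scalar gain, a schema version, and a JSON metadata blob.  Round-trips are
bit-exact on all arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .filterbank import ORIENTATIONS
from .gsm import GSMComponent
from .state import MGSMState

__all__ = ["SCHEMA_VERSION", "save_state", "load_state"]

SCHEMA_VERSION = 1


class StateIOError(IOError):
    pass


def save_state(state: MGSMState, path) -> None:
    arrays = {
        "schema_version": np.array(SCHEMA_VERSION),
        "priors": state.priors,
        "sigma_c": state.sigma_c.Sigma,
        "scale_c": np.array(state.sigma_c.scale),
        "metadata_json": np.array(json.dumps(state.metadata, default=str)),
    }
    for t in ORIENTATIONS:
        key = f"{int(t)}"
        arrays[f"sigma_cn_{key}"] = state.sigma_cn[t].Sigma
        arrays[f"scale_cn_{key}"] = np.array(state.sigma_cn[t].scale)
        arrays[f"sigma_n_{key}"] = state.sigma_n[t].Sigma
        arrays[f"scale_n_{key}"] = np.array(state.sigma_n[t].scale)
    np.savez(path, **arrays)


def load_state(path) -> MGSMState:
    p = Path(path)
    if not p.exists():
        raise StateIOError(f"state file not found: {p}")
    try:
        with np.load(p, allow_pickle=False) as z:
            version = int(z["schema_version"])
            if version != SCHEMA_VERSION:
                raise StateIOError(
                    f"state file {p} has schema version {version}, "
                    f"expected {SCHEMA_VERSION}")
            priors = z["priors"]
            sigma_c = GSMComponent(z["sigma_c"], scale=float(z["scale_c"]))
            sigma_cn = {
                t: GSMComponent(z[f"sigma_cn_{int(t)}"],
                                scale=float(z[f"scale_cn_{int(t)}"]))
                for t in ORIENTATIONS
            }
            sigma_n = {
                t: GSMComponent(z[f"sigma_n_{int(t)}"],
                                scale=float(z[f"scale_n_{int(t)}"]))
                for t in ORIENTATIONS
            }
            metadata = json.loads(str(z["metadata_json"]))
    except StateIOError:
        raise
    except Exception as exc:
        raise StateIOError(f"cannot read state file {p}: {exc}") from exc
    return MGSMState(
        prior_nonshared=float(priors[0]),
        prior_shared={t: float(priors[1 + i])
                      for i, t in enumerate(ORIENTATIONS)},
        sigma_c=sigma_c,
        sigma_cn=sigma_cn,
        sigma_n=sigma_n,
        metadata=metadata,
    )
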