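"""On-disk formats: the HDF5 epochs container and the run configuration.

Container layout::

    /subjects/<id>/sources/<name>/conditions/<label>
        attrs: srate (Hz), t_start (s), ear, units
        data:  float32, trials x samples

Condition labels are the strings "none", "-5", "0", "5", "10", "20".  A JSON
sidecar (``<path>.json``) written next to a simulated container records the
full simulation configuration including the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .exceptions import FormatError, InvalidConfigError
from .synth import EpochSet, SimConfig
from .windows import ALPHA, BASELINE_WINDOW, GAMMA, RESPONSE_WINDOW, THETA

__all__ = ["write_epochs", "read_epochs", "RunConfig"]


def write_epochs(path, epochs, config: SimConfig | None = None) -> Path:
    """Write EpochSets to the HDF5 container; optionally emit a config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        for ep in epochs:
            grp = h5.require_group(
                f"subjects/{ep.subject}/sources/{ep.source}/conditions/{ep.condition}"
            )
            grp.create_dataset("data", data=ep.data.astype(np.float32))
            grp.attrs["srate"] = float(ep.srate)
            grp.attrs["t_start"] = float(ep.t_start)
            grp.attrs["ear"] = ep.ear
            grp.attrs["units"] = ep.units
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(_config_to_jsonable(config), indent=2))
    return path


def _config_to_jsonable(config: SimConfig) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): conv(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list)):
            return [conv(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return conv(config)


def read_epochs(path) -> list[EpochSet]:
    """Read every EpochSet from a container, validating layout and invariants."""
    path = Path(path)
    epochs: list[EpochSet] = []
    with h5py.File(path, "r") as h5:
        if "subjects" not in h5:
            raise FormatError(f"{path}: missing top-level 'subjects' group")
        for sid, sgrp in h5["subjects"].items():
            if "sources" not in sgrp:
                raise FormatError(f"subjects/{sid}: missing 'sources' group")
            for source, ogrp in sgrp["sources"].items():
                if "conditions" not in ogrp:
                    raise FormatError(f"subjects/{sid}/sources/{source}: missing 'conditions'")
                for cond, cgrp in ogrp["conditions"].items():
                    where = f"subjects/{sid}/sources/{source}/conditions/{cond}"
                    if "data" not in cgrp:
                        raise FormatError(f"{where}: missing 'data' dataset")
                    for attr in ("srate", "t_start", "ear", "units"):
                        if attr not in cgrp.attrs:
                            raise FormatError(f"{where}: missing attribute {attr!r}")
                    data = np.asarray(cgrp["data"], dtype=np.float64)
                    if data.ndim != 2 or data.shape[0] == 0:
                        raise FormatError(f"{where}: data must be non-empty trials x samples")
                    try:
                        epochs.append(
                            EpochSet(
                                data=data,
                                srate=float(cgrp.attrs["srate"]),
                                t_start=float(cgrp.attrs["t_start"]),
                                subject=sid,
                                source=source,
                                condition=cond,
                                ear=str(cgrp.attrs["ear"]),
                                units=str(cgrp.attrs["units"]),
                            )
                        )
                    except InvalidConfigError as exc:
                        raise FormatError(f"{where}: {exc}") from exc
    if not epochs:
        raise FormatError(f"{path}: container holds no epochs")
    return epochs


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs besides the epochs themselves."""

    epochs_path: str
    out_dir: str
    f_min: float = 5.0
    f_max: float = 55.0
    n_bins: int = 25
    c0: float = 3.0
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    response_window: tuple[float, float] = RESPONSE_WINDOW
    bands: dict = field(default_factory=lambda: {"theta": THETA, "alpha": ALPHA, "gamma": GAMMA})
    plv_windows: dict = field(
        default_factory=lambda: {"response": RESPONSE_WINDOW, "late": (0.10, 0.30)}
    )
    pairs: tuple | None = None        # None -> all source pairs present
    band_mode: str = "broad"          # "broad" | "custom"
    zero_label: str = "none"
    n_perm: int = 1000
    n_shuffle: int = 200
    alpha_pixel: float = 0.01
    alpha_group: float = 0.001
    alpha_dunnett: float = 0.05
    min_cluster: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for a, name in (
            (self.alpha_pixel, "alpha_pixel"),
            (self.alpha_group, "alpha_group"),
            (self.alpha_dunnett, "alpha_dunnett"),
        ):
            if not (0 < a < 1):
                raise InvalidConfigError(f"{name} must be in (0, 1), got {a}")
        if self.band_mode not in ("broad", "custom"):
            raise InvalidConfigError(f"band_mode must be 'broad' or 'custom', got {self.band_mode!r}")
        for label, (t0, t1) in {"baseline": self.baseline_window,
                                "response": self.response_window,
                                **{f"plv:{k}": v for k, v in self.plv_windows.items()}}.items():
            if not (t0 < t1):
                raise InvalidConfigError(f"window {label} requires t0 < t1, got [{t0}, {t1}]")

    def validate_against_epochs(self, epochs) -> None:
        """Check every analysis window fits inside the epochs before computing."""
        for ep in epochs:
            t0 = ep.t_start
            t1 = ep.t_start + (ep.n_samples - 1) / ep.srate
            for label, (w0, w1) in {"baseline": self.baseline_window,
                                    "response": self.response_window,
                                    **{f"plv:{k}": v for k, v in self.plv_windows.items()}}.items():
                if not (t0 <= w0 and w1 <= t1):
                    raise InvalidConfigError(
                        f"window {label} [{w0}, {w1}] s outside epoch [{t0}, {t1}] s "
                        f"({ep.subject}/{ep.source}/{ep.condition})"
                    )
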