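"""The 350-26-1 feed-forward sizing network.

The network maps the first 350 lags of a normalized intensity
autocorrelation directly to the hydrodynamic diameter.  Architecture:

* input layer: 350 units, one per ACR lag, fed in raw units (normalized
  ACR values already share a common physical scale; per-lag range
  rescaling would amplify the noise-dominated late lags — measurably
  hurting generalization — so the stored input map defaults to identity);
* hidden layer: 26 tanh units;
* output layer: 1 tanh unit, whose activation is mapped affinely back
  from [-0.9, 0.9] to the *logarithm* of the diameter over the training
  range (the log equalizes relative error across 25-6000 nm; the 0.9
  margin keeps the output sigmoid away from saturation).

Training is full-batch Levenberg-Marquardt on the scaled-target residuals
with an analytic Jacobian.  Because the parameter count (9153) exceeds the
number of training series in typical desk-scale corpora, the damped
Gauss-Newton step is solved in data space through the push-through
identity  (J^T J + lambda I)^{-1} J^T r = J^T (J J^T + lambda I)^{-1} r,
which turns the per-iteration factorization from O(p^3) into O(n^3).

Training stops when the training-split R-value (Pearson correlation
between predicted and target diameters) rounds to 1 at ``r_stop_digits``
digits, when the validation error has not improved for six consecutive
accepted steps (the weights with the best validation error are restored),
or at the iteration cap.  Prediction is pure matrix arithmetic — no
iteration — which is what makes the network thousands of times cheaper
per series than the reference fit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .acr import AutocorrelationCurve
from .errors import InputSizeError, ModelIOError, ParameterDomainError, TrainingError
from .simulate import TrainingCorpus

MODEL_FORMAT = "dlsann-model"
MODEL_VERSION = 1

#: Diameter ranges (nm) over which the error report aggregates, and the
#: lower cutoff below which the method is documented as unreliable.
ERROR_RANGES_NM = ((25.0, 70.0), (70.0, 150.0), (150.0, 350.0), (350.0, 6000.0))
RELIABLE_MIN_NM = 25.0

TARGET_SPAN = 0.9  # scaled targets live in [-0.9, 0.9]


@dataclass
class AnnModel:
    """Weights, biases and scaling maps of the trained network."""

    hidden_weights: np.ndarray  # (n_hidden, n_input)
    hidden_biases: np.ndarray  # (n_hidden,)
    output_weights: np.ndarray  # (1, n_hidden)
    output_bias: float
    input_offset: np.ndarray  # (n_input,) per-lag affine map: (x - offset) * scale
    input_scale: np.ndarray  # (n_input,)
    target_offset: float  # transformed diameter at scaled 0
    target_scale: float  # scaled units per transformed-diameter unit
    target_transform: str = "log"  # "log" (ln of metres) | "linear" (metres)
    output_transfer: str = "tanh"  # "tanh" | "linear"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.hidden_biases = np.asarray(self.hidden_biases, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float).reshape(1, -1)
        self.input_offset = np.asarray(self.input_offset, dtype=float)
        self.input_scale = np.asarray(self.input_scale, dtype=float)
        for arr in (self.hidden_weights, self.hidden_biases, self.output_weights,
                    self.input_offset, self.input_scale):
            if not np.all(np.isfinite(arr)):
                raise ParameterDomainError("model contains non-finite parameters")
        if self.target_scale == 0:
            raise ParameterDomainError("target scaling is not invertible (scale 0)")
        if self.target_transform not in ("log", "linear"):
            raise ParameterDomainError(f"unknown target transform {self.target_transform!r}")
        if self.output_transfer not in ("tanh", "linear"):
            raise ParameterDomainError(f"unknown output transfer {self.output_transfer!r}")

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.hidden_weights.shape[1], self.hidden_weights.shape[0], 1)


@dataclass
class TrainingReport:
    """Provenance of one training run."""

    iterations: int
    final_r_value: float
    split_sizes: tuple[int, int, int]  # train / val / test
    stop_reason: str  # "r-converged" | "max-iter" | "val-stall" | "lm-stalled"
    seed: int
    final_train_sse: float
    loss_history: list = field(default_factory=list)  # SSE after each accepted step


@dataclass
class ErrorReport:
    """Relative errors of the network against the reference-fit diameters."""

    errors_percent: np.ndarray  # signed, one per corpus row
    diameters_true: np.ndarray  # m
    range_max_abs: dict  # {(lo_nm, hi_nm): max |err| %}
    below_range: dict  # {"n": ..., "min": ..., "max": ...} for d_true < 25 nm


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def _forward_scaled(model: AnnModel, x_scaled: np.ndarray) -> np.ndarray:
    """Network output (scaled units) for pre-scaled inputs, shape (n, p)."""
    h = np.tanh(x_scaled @ model.hidden_weights.T + model.hidden_biases)
    s = h @ model.output_weights.ravel() + model.output_bias
    return np.tanh(s) if model.output_transfer == "tanh" else s


def _scale_inputs(model: AnnModel, x: np.ndarray) -> np.ndarray:
    return (x - model.input_offset) * model.input_scale


def _unscale_target(model: AnnModel, y_scaled: np.ndarray) -> np.ndarray:
    t = y_scaled / model.target_scale + model.target_offset
    return np.exp(t) if model.target_transform == "log" else t


def predict_batch(model: AnnModel, acr_matrix: np.ndarray) -> np.ndarray:
    """Diameters (m) for a matrix of normalized ACRs, shape (n, n_lags).

    Pure matrix arithmetic; no per-row iteration.
    """
    x = np.atleast_2d(np.asarray(acr_matrix, dtype=float))
    if x.shape[1] != model.layer_sizes[0]:
        raise InputSizeError(
            f"expected {model.layer_sizes[0]} lags per curve, got {x.shape[1]}"
        )
    return _unscale_target(model, _forward_scaled(model, _scale_inputs(model, x)))


def predict(model: AnnModel, curve: AutocorrelationCurve) -> float:
    """Diameter (m) for one normalized autocorrelation curve."""
    if not curve.normalized:
        raise InputSizeError("predict requires a normalized curve")
    return float(predict_batch(model, curve.lag_values[None, :])[0])


def relative_error(d_ann: float, d_ref: float) -> float:
    """Signed relative error (d_ann - d_ref)/d_ref * 100, percent."""
    d_ann = np.asarray(d_ann, dtype=float)
    d_ref = np.asarray(d_ref, dtype=float)
    if np.any(d_ref <= 0):
        raise ParameterDomainError("reference diameter must be > 0")
    out = (d_ann - d_ref) / d_ref * 100.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _split_indices(n: int, seed: int, fractions=(0.70, 0.15, 0.15)):
    """Deterministic shuffled train/val/test split."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def _init_params(n_in: int, n_hidden: int, seed: int):
    rng = np.random.default_rng(seed)
    w1 = rng.uniform(-0.5, 0.5, (n_hidden, n_in)) / np.sqrt(n_in)
    b1 = rng.uniform(-0.5, 0.5, n_hidden) / np.sqrt(n_in)
    w2 = rng.uniform(-0.5, 0.5, (1, n_hidden)) / np.sqrt(n_hidden)
    b2 = float(rng.uniform(-0.5, 0.5)) / np.sqrt(n_hidden)
    return w1, b1, w2, b2


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2.ravel(), [b2]])


def _unpack(p, n_in, n_hidden):
    k = n_hidden * n_in
    w1 = p[:k].reshape(n_hidden, n_in)
    b1 = p[k : k + n_hidden]
    w2 = p[k + n_hidden : k + 2 * n_hidden].reshape(1, n_hidden)
    b2 = float(p[k + 2 * n_hidden])
    return w1, b1, w2, b2


def _forward_params(x, w1, b1, w2, b2, output_transfer):
    h = np.tanh(x @ w1.T + b1)
    s = h @ w2.ravel() + b2
    o = np.tanh(s) if output_transfer == "tanh" else s
    return h, o


def _jacobian(x, h, o, w2, output_transfer):
    """J[n, p]: derivative of the network output wrt every parameter."""
    n, n_in = x.shape
    n_hidden = h.shape[1]
    do_ds = (1.0 - o**2) if output_transfer == "tanh" else np.ones_like(o)
    g = do_ds[:, None] * w2.ravel() * (1.0 - h**2)  # (n, n_hidden) = do/d(b1)
    j = np.empty((n, n_hidden * n_in + 2 * n_hidden + 1))
    j[:, : n_hidden * n_in] = (g[:, :, None] * x[:, None, :]).reshape(n, -1)
    j[:, n_hidden * n_in : n_hidden * n_in + n_hidden] = g
    j[:, n_hidden * n_in + n_hidden : n_hidden * n_in + 2 * n_hidden] = do_ds[:, None] * h
    j[:, -1] = do_ds
    return j


def _lm_step(j: np.ndarray, r: np.ndarray, lam: float) -> np.ndarray:
    """Damped Gauss-Newton step delta = -(J^T J + lam I)^{-1} J^T r."""
    n, p = j.shape
    if n < p:
        a = j @ j.T
        a[np.diag_indices_from(a)] += lam
        u = cho_solve(cho_factor(a), r)
        return -(j.T @ u)
    a = j.T @ j
    a[np.diag_indices_from(a)] += lam
    return -cho_solve(cho_factor(a), j.T @ r)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else 0.0


def train(
    corpus: TrainingCorpus,
    seed: int = 0,
    max_iterations: int = 150,
    n_hidden: int = 26,
    output_transfer: str = "tanh",
    target_transform: str = "log",
    input_scaling: str = "none",
    r_stop_digits: int = 8,
    val_stall_checks: int = 6,
    restore_best_val: bool = True,
    use_true_diameters: bool = False,
) -> tuple[AnnModel, TrainingReport]:
    """Train the sizing network on a corpus with Levenberg-Marquardt.

    Targets are the reference-fit diameters (``use_true_diameters=True``
    substitutes the ground-truth grid, useful for ablations). The split is
    70/15/15 train/validation/test, shuffled deterministically from ``seed``.
    ``input_scaling`` is ``"none"`` (raw ACR values, default) or ``"minmax"``
    (per-lag affine map to [-1, 1] computed on the training split).
    """
    if corpus.n_series < 10:
        raise TrainingError(f"corpus of {corpus.n_series} rows is too small to split")
    targets_m = (
        corpus.diameters_true if use_true_diameters else corpus.diameters_reference
    )
    if np.any(~np.isfinite(targets_m)):
        raise TrainingError("corpus targets contain non-finite diameters")
    if np.ptp(targets_m) == 0:
        raise TrainingError("degenerate targets: zero diameter variance")
    if np.any(targets_m <= 0):
        raise TrainingError("corpus targets contain non-positive diameters")

    idx_train, idx_val, idx_test = _split_indices(corpus.n_series, seed)
    x_all = corpus.acr_matrix
    n_in = x_all.shape[1]
    x_tr_raw = x_all[idx_train]

    if input_scaling == "minmax":
        lo = x_tr_raw.min(axis=0)
        hi = x_tr_raw.max(axis=0)
        span = hi - lo
        scale = np.where(span > 0, 2.0 / np.where(span > 0, span, 1.0), 0.0)
        offset = (lo + hi) / 2.0
    elif input_scaling == "none":
        offset = np.zeros(n_in)
        scale = np.ones(n_in)
    else:
        raise TrainingError(f"unknown input_scaling {input_scaling!r}")

    # target scaling: transformed training-target range -> [-0.9, 0.9]
    t_all = np.log(targets_m) if target_transform == "log" else targets_m.copy()
    t_tr = t_all[idx_train]
    t_lo, t_hi = float(t_tr.min()), float(t_tr.max())
    if t_hi == t_lo:
        raise TrainingError("degenerate targets: zero diameter variance")
    target_scale = 2.0 * TARGET_SPAN / (t_hi - t_lo)
    target_offset = (t_lo + t_hi) / 2.0

    def scale_x(x):
        return (x - offset) * scale

    def scale_t(t):
        return (t - target_offset) * target_scale

    x_tr = scale_x(x_tr_raw)
    y_tr = scale_t(t_tr)
    x_val = scale_x(x_all[idx_val])
    y_val = scale_t(t_all[idx_val])

    w1, b1, w2, b2 = _init_params(n_in, n_hidden, seed)
    params = _pack(w1, b1, w2, b2)
    h, o = _forward_params(x_tr, w1, b1, w2, b2, output_transfer)
    r = o - y_tr
    loss = float(r @ r)

    lam = 1e-3
    r_threshold = 1.0 - 0.5 * 10.0 ** (-r_stop_digits)  # rounds to 1 at r_stop_digits
    best_val = np.inf
    best_params = params.copy()
    stall = 0
    stop_reason = "max-iter"
    iterations = 0
    loss_history: list[float] = []

    for iterations in range(1, max_iterations + 1):
        j = _jacobian(x_tr, h, o, w2, output_transfer)
        if not np.all(np.isfinite(j)):
            raise TrainingError(f"non-finite Jacobian at iteration {iterations}")
        accepted = False
        while lam < 1e12:
            delta = _lm_step(j, r, lam)
            cand = params + delta
            cw1, cb1, cw2, cb2 = _unpack(cand, n_in, n_hidden)
            ch, co = _forward_params(x_tr, cw1, cb1, cw2, cb2, output_transfer)
            cr = co - y_tr
            closs = float(cr @ cr)
            if np.isfinite(closs) and closs < loss:
                params, w1, b1, w2, b2 = cand, cw1, cb1, cw2, cb2
                h, o, r, loss = ch, co, cr, closs
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            stop_reason = "lm-stalled"
            break
        loss_history.append(loss)

        if len(y_val):
            _, o_val = _forward_params(x_val, w1, b1, w2, b2, output_transfer)
            val_loss = float(np.sum((o_val - y_val) ** 2))
            if val_loss < best_val * (1.0 - 1e-9):
                best_val = val_loss
                best_params = params.copy()
                stall = 0
            else:
                stall += 1
                if stall >= val_stall_checks:
                    stop_reason = "val-stall"
                    break

        r_value = _pearson(o, y_tr)
        if r_value >= r_threshold:
            stop_reason = "r-converged"
            break

    if restore_best_val and len(y_val) and np.isfinite(best_val):
        params = best_params
        w1, b1, w2, b2 = _unpack(params, n_in, n_hidden)
        h, o = _forward_params(x_tr, w1, b1, w2, b2, output_transfer)
        r = o - y_tr
        loss = float(r @ r)

    final_r = _pearson(o, y_tr)
    model = AnnModel(
        hidden_weights=w1,
        hidden_biases=b1,
        output_weights=w2,
        output_bias=b2,
        input_offset=offset,
        input_scale=scale,
        target_offset=target_offset,
        target_scale=target_scale,
        target_transform=target_transform,
        output_transfer=output_transfer,
        provenance={
            "corpus_sha256": hashlib.sha256(
                np.ascontiguousarray(corpus.acr_matrix).tobytes()
            ).hexdigest(),
            "n_series": int(corpus.n_series),
            "seed": int(seed),
            "split_fractions": [0.70, 0.15, 0.15],
            "targets": "true" if use_true_diameters else "reference-fit",
        },
    )
    report = TrainingReport(
        iterations=iterations,
        final_r_value=final_r,
        split_sizes=(len(idx_train), len(idx_val), len(idx_test)),
        stop_reason=stop_reason,
        seed=seed,
        final_train_sse=loss,
        loss_history=loss_history,
    )
    return model, report


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate(model: AnnModel, corpus: TrainingCorpus) -> ErrorReport:
    """Relative errors of the network over a whole corpus, aggregated by
    true-diameter range. Series below the reliable lower cutoff are reported
    separately and excluded from the four ranges."""
    d_ann = predict_batch(model, corpus.acr_matrix)
    errs = relative_error(d_ann, corpus.diameters_reference)
    d_nm = corpus.diameters_true * 1e9

    range_max: dict = {}
    for lo, hi in ERROR_RANGES_NM:
        closed = hi == ERROR_RANGES_NM[-1][1]
        mask = (d_nm >= lo) & ((d_nm <= hi) if closed else (d_nm < hi))
        range_max[(lo, hi)] = float(np.max(np.abs(errs[mask]))) if mask.any() else float("nan")

    below = d_nm < RELIABLE_MIN_NM
    below_range = {
        "n": int(below.sum()),
        "min": float(errs[below].min()) if below.any() else float("nan"),
        "max": float(errs[below].max()) if below.any() else float("nan"),
    }
    return ErrorReport(
        errors_percent=errs,
        diameters_true=corpus.diameters_true,
        range_max_abs=range_max,
        below_range=below_range,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _payload(model: AnnModel) -> dict:
    return {
        "layer_sizes": list(model.layer_sizes),
        "hidden_weights": model.hidden_weights.tolist(),
        "hidden_biases": model.hidden_biases.tolist(),
        "output_weights": model.output_weights.tolist(),
        "output_bias": model.output_bias,
        "input_offset": model.input_offset.tolist(),
        "input_scale": model.input_scale.tolist(),
        "target_offset": model.target_offset,
        "target_scale": model.target_scale,
        "target_transform": model.target_transform,
        "output_transfer": model.output_transfer,
        "provenance": model.provenance,
    }


def save_model(model: AnnModel, path: str | Path) -> None:
    """Canonical, checksummed JSON container; re-saving a loaded model yields
    a byte-identical file."""
    payload = _payload(model)
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "payload": payload,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))


def load_model(path: str | Path) -> AnnModel:
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelIOError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ModelIOError(f"{path} is not a {MODEL_FORMAT} file")
    if doc.get("version") != MODEL_VERSION:
        raise ModelIOError(
            f"unsupported model version {doc.get('version')!r} (expected {MODEL_VERSION})"
        )
    payload = doc.get("payload")
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    if hashlib.sha256(blob.encode()).hexdigest() != doc.get("sha256"):
        raise ModelIOError(f"checksum mismatch in {path} (corrupt or truncated file)")
    return AnnModel(
        hidden_weights=np.array(payload["hidden_weights"]),
        hidden_biases=np.array(payload["hidden_biases"]),
        output_weights=np.array(payload["output_weights"]),
        output_bias=float(payload["output_bias"]),
        input_offset=np.array(payload["input_offset"]),
        input_scale=np.array(payload["input_scale"]),
        target_offset=float(payload["target_offset"]),
        target_scale=float(payload["target_scale"]),
        target_transform=payload["target_transform"],
        output_transfer=payload["output_transfer"],
        provenance=payload.get("provenance", {}),
    )
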