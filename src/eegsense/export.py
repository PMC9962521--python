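"""Embedded-ready model export: C-like decision source plus a
coefficient sidecar, and an interpreter that replays the emitted text.

The emitted artifact is what would be compiled into a sensor firmware:
a single linear decision expression for the SVM / logistic regression,
a nested if-then-else listing for the tree, or a comparison chain for
the threshold rule.  The replay interpreter parses the *text* (not the
coefficient table), so a round-trip test genuinely checks that the
exported source encodes the same decision function as the native
model.  Floats are emitted with ``repr`` precision, which round-trips
exactly, so replayed scores match native scores bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import TrainedModel

__version_tag__ = "eegsense-export-1"


@dataclass
class EmbeddedArtifact:
    kind: str
    source: str                    # C-like decision function body
    coefficients: dict
    feature_order: list[str]
    metadata: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        """Write the source as a .c-like file with a JSON sidecar."""
        path = Path(path)
        path.write_text(self.source)
        sidecar = {
            "kind": self.kind,
            "coefficients": self.coefficients,
            "feature_order": self.feature_order,
            "metadata": self.metadata,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )


def _fmt_key(key) -> str:
    return "__".join(str(part) for part in key) if isinstance(key, tuple) else str(key)


def _linear_source(model: TrainedModel) -> str:
    terms = " + ".join(
        f"({repr(float(w))}) * x[{j}]" for j, w in enumerate(model.weights)
    )
    lines = [
        f"/* feature order: "
        f"{', '.join(_fmt_key(k) for k in model.feature_keys)} */",
        "int classify(const double *x) {",
        f"    double score = {terms} + ({repr(float(model.bias))});",
    ]
    if model.kind == "logreg":
        lines.append("    double prob = 1.0 / (1.0 + exp(-score));")
        lines.append("    return prob >= 0.5 ? 1 : 0;")
    else:
        lines.append("    return score > 0.0 ? 1 : 0;")
    lines.append("}")
    return "\n".join(lines)


def _tree_source(model: TrainedModel) -> str:
    def emit(node: dict, depth: int) -> list[str]:
        pad = "    " * depth
        if "label" in node:
            return [f"{pad}return {int(node['label'])};"]
        out = [f"{pad}if (x[{node['feature']}] <= {repr(float(node['threshold']))}) {{"]
        out += emit(node["left"], depth + 1)
        out.append(f"{pad}}} else {{")
        out += emit(node["right"], depth + 1)
        out.append(f"{pad}}}")
        return out

    lines = [
        f"/* feature order: "
        f"{', '.join(_fmt_key(k) for k in model.feature_keys)} */",
        "int classify(const double *x) {",
    ]
    lines += emit(model.rules, 1)
    lines.append("}")
    return "\n".join(lines)


def _threshold_source(model: TrainedModel) -> str:
    lines = [
        f"/* feature order: "
        f"{', '.join(_fmt_key(k) for k in model.feature_keys)} */",
        "int classify(const double *x) {",
    ]
    if model.gate is not None:
        g = model.gate
        op = ">=" if g["direction"] > 0 else "<="
        fired_label = g["fire_on"]
        if fired_label == 1:
            lines.append(
                f"    if (x[{g['feature']}] {op} {repr(float(g['threshold']))}) "
                f"return 1;"
            )
        else:
            # NPV-pure gate: fires when its rule says control
            lines.append(
                f"    if (!(x[{g['feature']}] {op} {repr(float(g['threshold']))})) "
                f"return 0;"
            )
    p = model.primary
    op = ">=" if model.directions[p] > 0 else "<="
    lines.append(
        f"    return x[{p}] {op} {repr(float(model.thresholds[p]))} ? 1 : 0;"
    )
    lines.append("}")
    return "\n".join(lines)


def export_model(model: TrainedModel) -> EmbeddedArtifact:
    """Emit a trained model as a self-contained C-like artifact."""
    if model.kind in ("svm_linear", "logreg"):
        source = _linear_source(model)
        coeffs = {"weights": model.weights, "bias": model.bias}
    elif model.kind == "tree":
        source = _tree_source(model)
        coeffs = {"rules": model.rules}
    elif model.kind == "threshold":
        source = _threshold_source(model)
        coeffs = {"thresholds": model.thresholds,
                  "directions": model.directions,
                  "primary": model.primary, "gate": model.gate}
    else:
        raise ValueError(f"unsupported model kind {model.kind!r}")
    digest = hashlib.sha256(model.to_json().encode()).hexdigest()[:16]
    return EmbeddedArtifact(
        kind=model.kind,
        source=source,
        coefficients=coeffs,
        feature_order=[_fmt_key(k) for k in model.feature_keys],
        metadata={"generator": __version_tag__, "model_hash": digest},
    )


# ---------------------------------------------------------------------------
# replay interpreter

_FLOAT = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?|[-+]?inf|[-+]?nan"


def _replay_one(lines: list[str], x: np.ndarray) -> int:
    """Execute the constrained emitted grammar on one input row."""
    env: dict[str, float] = {}
    i = 0

    def evaluate_linear(expr: str) -> float:
        total = 0.0
        for coef, idx in re.findall(rf"\(({_FLOAT})\) \* x\[(\d+)\]", expr):
            total += float(coef) * x[int(idx)]
        tail = re.search(rf"\+ \(({_FLOAT})\)\s*;?\s*$", expr)
        if tail:
            total += float(tail.group(1))
        return total

    def compare(line: str) -> bool:
        m = re.search(
            rf"(!?)\(?x\[(\d+)\] (>=|<=) ({_FLOAT})\)?", line
        )
        neg, idx, op, thr = m.groups()
        res = x[int(idx)] >= float(thr) if op == ">=" else x[int(idx)] <= float(thr)
        return (not res) if neg else res

    def run_block(i: int) -> tuple[int | None, int]:
        """Execute statements from line i until a return or block end."""
        while i < len(lines):
            line = lines[i].strip()
            if line.startswith("/*") or line.startswith("int classify"):
                i += 1
                continue
            if line.startswith("}"):
                return None, i
            if line.startswith("double score"):
                env["score"] = evaluate_linear(line.split("=", 1)[1])
                i += 1
                continue
            if line.startswith("double prob"):
                env["prob"] = 1.0 / (1.0 + np.exp(-env["score"]))
                i += 1
                continue
            if line.startswith("return"):
                body = line[len("return"):].strip().rstrip(";")
                if "?" in body:
                    cond, rest = body.split("?", 1)
                    yes, no = (s.strip() for s in rest.split(":"))
                    cond = cond.strip()
                    if cond.startswith("score"):
                        ok = env["score"] > 0.0
                    elif cond.startswith("prob"):
                        ok = env["prob"] >= 0.5
                    else:
                        ok = compare(cond)
                    return int(yes) if ok else int(no), i
                return int(body), i
            if line.startswith("if"):
                cond_ok = compare(line)
                if "return" in line:  # single-line guard: if (...) return L;
                    if cond_ok:
                        return int(re.search(r"return (\d+);", line).group(1)), i
                    i += 1
                    continue
                # block if/else
                then_end = _match_brace(lines, i)
                else_end = _match_brace(lines, then_end)
                if cond_ok:
                    label, _ = run_block(i + 1)
                else:
                    label, _ = run_block(then_end + 1)
                if label is not None:
                    return label, i
                i = else_end + 1
                continue
            i += 1
        return None, i

    label, _ = run_block(0)
    if label is None:
        raise ValueError("emitted source produced no decision")
    return label


def _match_brace(lines: list[str], open_line: int) -> int:
    """Line index closing the first '{' found at or after ``open_line``."""
    depth = 0
    started = False
    for j in range(open_line, len(lines)):
        for ch in lines[j]:
            if ch == "{":
                depth += 1
                started = True
            elif ch == "}" and started:
                depth -= 1
                if depth == 0:
                    return j
    raise ValueError("unbalanced braces in emitted source")


def replay_artifact(artifact: EmbeddedArtifact, X) -> np.ndarray:
    """Parse and evaluate the emitted source on rows of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    lines = artifact.source.splitlines()
    return np.array([_replay_one(lines, x) for x in X])
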