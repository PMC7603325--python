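"""C99 source emission for deployed trees.

A tree is rendered as a self-contained translation unit: one static
function per *distinct* feature used (emitted once, mirroring shared
extractor code on the MCU) and a ``predict`` function that is a nested
hierarchy of conditionals.  Feature extractors are called inside the
conditional for the node that needs them, so only features on the taken
root-to-leaf path are ever computed.  The generated code uses only the C
standard library (math.h) and compiles warning-free with
``-std=c99 -Wall -Wextra``.
"""

from __future__ import annotations

from .errors import SchemaError
from .features import FeatureCatalogue
from .trees import CostedTree, Leaf, Node

# Extractor templates; {fn} is the function name. All mirror the scalar
# Python extractors in aioa.features exactly (same operation order).
C_TEMPLATES: dict[str, str] = {
    "mean": """static double {fn}(const double *w, size_t n) {{
    double s = 0.0;
    for (size_t i = 0; i < n; i++) s += w[i];
    return s / (double)n;
}}""",
    "variance": """static double {fn}(const double *w, size_t n) {{
    double m = 0.0, s = 0.0;
    for (size_t i = 0; i < n; i++) m += w[i];
    m /= (double)n;
    for (size_t i = 0; i < n; i++) s += (w[i] - m) * (w[i] - m);
    return s / (double)n;
}}""",
    "std": """static double {fn}(const double *w, size_t n) {{
    double m = 0.0, s = 0.0;
    for (size_t i = 0; i < n; i++) m += w[i];
    m /= (double)n;
    for (size_t i = 0; i < n; i++) s += (w[i] - m) * (w[i] - m);
    return sqrt(s / (double)n);
}}""",
    "min": """static double {fn}(const double *w, size_t n) {{
    double out = w[0];
    for (size_t i = 0; i < n; i++) if (w[i] < out) out = w[i];
    return out;
}}""",
    "max": """static double {fn}(const double *w, size_t n) {{
    double out = w[0];
    for (size_t i = 0; i < n; i++) if (w[i] > out) out = w[i];
    return out;
}}""",
    "range": """static double {fn}(const double *w, size_t n) {{
    double lo = w[0], hi = w[0];
    for (size_t i = 0; i < n; i++) {{
        if (w[i] < lo) lo = w[i];
        if (w[i] > hi) hi = w[i];
    }}
    return hi - lo;
}}""",
    "rms": """static double {fn}(const double *w, size_t n) {{
    double s = 0.0;
    for (size_t i = 0; i < n; i++) s += w[i] * w[i];
    return sqrt(s / (double)n);
}}""",
    "crest": """static double {fn}(const double *w, size_t n) {{
    double s = 0.0, hi = w[0];
    for (size_t i = 0; i < n; i++) {{
        s += w[i] * w[i];
        if (w[i] > hi) hi = w[i];
    }}
    s = sqrt(s / (double)n);
    if (s == 0.0) return 0.0;
    return hi / s;
}}""",
    "kurtosis": """static double {fn}(const double *w, size_t n) {{
    double m = 0.0, m2 = 0.0, m4 = 0.0;
    for (size_t i = 0; i < n; i++) m += w[i];
    m /= (double)n;
    for (size_t i = 0; i < n; i++) {{
        double d = w[i] - m;
        m2 += d * d;
        m4 += d * d * d * d;
    }}
    m2 /= (double)n;
    m4 /= (double)n;
    if (m2 == 0.0) return 0.0;
    return m4 / (m2 * m2);
}}""",
    "skewness": """static double {fn}(const double *w, size_t n) {{
    double m = 0.0, m2 = 0.0, m3 = 0.0;
    for (size_t i = 0; i < n; i++) m += w[i];
    m /= (double)n;
    for (size_t i = 0; i < n; i++) {{
        double d = w[i] - m;
        m2 += d * d;
        m3 += d * d * d;
    }}
    m2 /= (double)n;
    m3 /= (double)n;
    if (m2 == 0.0) return 0.0;
    return m3 / (m2 * sqrt(m2));
}}""",
    "meancross": """static double {fn}(const double *w, size_t n) {{
    double m = 0.0;
    int c = 0;
    for (size_t i = 0; i < n; i++) m += w[i];
    m /= (double)n;
    for (size_t i = 0; i + 1 < n; i++)
        if ((w[i] - m) * (w[i + 1] - m) < 0.0) c++;
    return (double)c;
}}""",
    "meanabsdiff": """static double {fn}(const double *w, size_t n) {{
    double s = 0.0;
    for (size_t i = 0; i + 1 < n; i++) s += fabs(w[i + 1] - w[i]);
    return s / (double)(n - 1);
}}""",
}

_MAIN = """
#include <stdio.h>
#include <stdlib.h>
#include <string.h>

/* Reads whitespace-separated doubles, %d per window, from stdin and
 * prints the predicted class name per window. */
int main(void) {
    double w[%d];
    for (;;) {
        size_t i;
        for (i = 0; i < %du; i++)
            if (scanf("%%lf", &w[i]) != 1) return 0;
        printf("%%s\\n", class_names[predict(w, %du)]);
    }
}
"""


def _render_node(node, fname: dict[str, str], class_index: dict[str, int],
                 indent: int) -> list[str]:
    pad = "    " * indent
    if isinstance(node, Leaf):
        return [f"{pad}return {class_index[node.klass]}; /* {node.klass} */"]
    fn = fname[node.feature]
    lines = [f"{pad}if ({fn}(w, n) <= {node.threshold!r}) {{"]
    lines += _render_node(node.left, fname, class_index, indent + 1)
    lines.append(f"{pad}}} else {{")
    lines += _render_node(node.right, fname, class_index, indent + 1)
    lines.append(f"{pad}}}")
    return lines


def render_tree_source(tree: CostedTree, catalogue: FeatureCatalogue,
                       window_length: int = 25,
                       include_main: bool = False) -> str:
    """Emit the tree as a C99 translation unit.

    ``include_main`` appends a small driver reading ``window_length``
    doubles per window from stdin and printing the predicted class name —
    used by the differential test against :meth:`CostedTree.predict_one`.
    """
    used = sorted(tree.features_used())
    fname = {}
    for f in used:
        if f not in catalogue:
            raise SchemaError(f"tree references feature {f!r} absent from catalogue")
        ex = catalogue.entries[f].extractor
        if ex not in C_TEMPLATES:
            raise SchemaError(f"feature {f!r}: no C template for extractor {ex!r}")
        fname[f] = f"feat_{f}"
    class_index = {c: k for k, c in enumerate(tree.classes)}
    parts = [
        "/* Generated decision-tree classifier (C99, standard library only). */",
        "#include <math.h>",
        "#include <stddef.h>",
        "",
        "static const char *class_names[] = {"
        + ", ".join(f'"{c}"' for c in tree.classes) + "};",
        "",
    ]
    for f in used:
        parts.append(C_TEMPLATES[catalogue.entries[f].extractor].format(fn=fname[f]))
        parts.append("")
    body = _render_node(tree.root, fname, class_index, 1)
    parts.append("int predict(const double *w, size_t n) {")
    if not used:
        parts.append("    (void)w; (void)n;")
    parts.extend(body)
    parts.append("}")
    src = "\n".join(parts) + "\n"
    if include_main:
        src += _MAIN % (window_length, window_length, window_length, window_length)
    else:
        src = src.replace("static const char *class_names[]",
                          "const char *class_names[]")
    return src
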