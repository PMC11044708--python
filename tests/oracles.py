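"""Independent brute-force oracles used by the test suite.

These deliberately use plain Python loops and definitional formulas so they
share no code path with the package implementations they check.
"""


def brute_force_moving_median(values, window=32, center=True):
    """Quadratic-time moving median under the package's window conventions:
    centered windows cover window//2 samples back and the rest forward,
    truncated symmetrically at the edges; the median of an even count is
    the mean of the two central order statistics."""
    v = [float(x) for x in values]
    n = len(v)
    back = window // 2
    fwd = window - back - 1
    out = []
    for i in range(n):
        if center:
            if i - back >= 0 and i + fwd <= n - 1:
                w = v[i - back:i + fwd + 1]
            else:
                m = min(i, n - 1 - i)
                w = v[i - m:i + m + 1]
        else:
            w = v[max(0, i - window + 1):i + 1]
        s = sorted(w)
        half = len(s) // 2
        out.append(s[half] if len(s) % 2 else 0.5 * (s[half - 1] + s[half]))
    return out


def brute_force_anova_ms(x):
    """Two-way ANOVA mean squares from the definitional sums of squares."""
    n = len(x)
    k = len(x[0])
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_err = sum((x[i][j] - row_means[i] - col_means[j] + grand) ** 2
                 for i in range(n) for j in range(k))
    return (ss_rows / (n - 1), ss_cols / (k - 1),
            ss_err / ((n - 1) * (k - 1)))


def brute_force_icc_a1(x):
    """Single-measure absolute-agreement two-way random ICC from the
    definitional ANOVA mean squares."""
    n = len(x)
    k = len(x[0])
    msr, msc, mse = brute_force_anova_ms(x)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
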