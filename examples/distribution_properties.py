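"""Moments and lifetime summaries of a power-modified Lindley law.

Builds PML(alpha=2, theta=1) and prints its headline summaries; every
closed form shown here is validated against numerical quadrature in the
package's test suite.
"""

from pmlindley import PML

d = PML(alpha=2.0, theta=1.0)

print(f"distribution        : {d}")
print(f"mean                : {d.mean:.6f}")
print(f"variance            : {d.var:.6f}")
print(f"median              : {d.median:.6f}")
print(f"skewness            : {d.skewness:.6f}")
print(f"kurtosis            : {d.kurtosis:.6f}")
print(f"P(X <= 1)           : {d.cdf(1.0):.6f}")
print(f"hazard at x=1       : {d.hazard(1.0):.6f}")
print(f"mean residual life at t=1   : {d.mean_residual_life(1.0):.6f}")
print(f"mean inactivity time at t=1 : {d.mean_inactivity_time(1.0):.6f}")
print(f"mean deviation about mean   : {d.mean_deviation('mean'):.6f}")
print(f"Lorenz curve at p=0.5       : {d.lorenz_curve(0.5):.6f}")

# The mean residual life answers: given survival to age t, how much longer
# does the unit live on average?  The Lorenz value says the poorest half of
# the population carries that fraction of the total 'mass' (here lifetime).
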