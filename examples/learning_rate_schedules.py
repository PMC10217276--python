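"""The four nonlinear learning-rate decay schedules.

Prints each schedule's rate at a few checkpoints of a 1000-iteration
horizon (initial rate 1, as a normalized profile): exponential and cosine
reach zero at T; gaussian and sigmoid decay smoothly at rates set by their
attenuation parameter.
"""

from visbrix import LRSchedule, lr_at

T = 1000
schedules = {
    "fixed": LRSchedule("fixed", eta0=1.0, T=T),
    "exponential (p=2)": LRSchedule("exponential", eta0=1.0, T=T, p=2.0),
    "cosine": LRSchedule("cosine", eta0=1.0, T=T),
    "gaussian": LRSchedule("gaussian", eta0=1.0, T=T),
    "sigmoid": LRSchedule("sigmoid", eta0=1.0, T=T),
}
checkpoints = [0, 250, 500, 750, 1000]

print(f"{'schedule':>18} " + " ".join(f"t={t:>5}" for t in checkpoints))
for name, s in schedules.items():
    vals = " ".join(f"{lr_at(s, t):>7.4f}" for t in checkpoints)
    print(f"{name:>18} {vals}")
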