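"""Shared physical constants of the goalkeeping scenario.

All lengths are in metres, times in seconds, angles in degrees unless noted.
The analysis frame is used throughout: +x rightward from the goalkeeper,
+y up, +z from the goal towards the pitch; the goal-line midpoint at ground
level is the origin.  The ball is kicked from the centreline, 23 m out.
"""

GOAL_WIDTH = 7.32
GOAL_HEIGHT = 2.44
HALF_GOAL_WIDTH = GOAL_WIDTH / 2.0

KICK_DISTANCE = 23.0

# The ball used for the aerodynamic simulation is regulation-sized; the
# rendered/contact ball is slightly larger (its circumference of 0.769 m
# corresponds to a 0.2447 m diameter).
AERO_DIAMETER = 0.22
CONTACT_DIAMETER = 0.2447
CONTACT_RADIUS = CONTACT_DIAMETER / 2.0
# Release height: the ball rests on the ground before the kick.
RELEASE_HEIGHT = CONTACT_RADIUS

SPIN_RATE_EXPERIMENTAL = 1800.0  # deg/s
SPIN_RATE_DUMMY = 900.0          # deg/s
SPIN_TILT_DEG = 15.0

FLIGHT_TIMES = (1.0, 1.2)
DUMMY_FLIGHT_TIME = 1.1
ARRIVAL_HEIGHT = 1.75
DUMMY_ARRIVAL_HEIGHTS = (1.75, 2.12, 2.49)
LATERAL_ARRIVALS = (-1.5, 0.0, 1.5)
DUMMY_LATERAL_ARRIVALS = (-1.5, -0.75, 0.0, 0.75, 1.5)

FRAME_RATE = 90.0
FRAME_DT = 1.0 / FRAME_RATE

# Simulated trajectories extend this far past the goal line.
END_MARGIN = 2.0

# Palm collider of the virtual hand: proximal-to-distal x width x thickness.
PALM_COLLIDER = (0.12, 0.10, 0.035)
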