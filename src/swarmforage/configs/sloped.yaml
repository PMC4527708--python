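# Sloped foraging environment (default experimental arena).
# Zones tile the long axis in order nest | cache | slope | source.
kind: arena
environment: sloped
length: 9.75          # m, long axis
width: 1.75           # m
zone_lengths: [1.5, 2.5, 3.75, 2.0]   # m; nest, cache, slope, source
slope_angle: 8.0      # degrees
n_source_items: 5     # items always present in the source area
speed_flat: 0.15      # m/s, nominal linear speed
speed_up: 0.015       # m/s, maximum climbing speed
speed_down: 0.23      # m/s, descending speed
item_slide_speed: 1.0 # m/s, free items sliding down the slope
scale: 1.0
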