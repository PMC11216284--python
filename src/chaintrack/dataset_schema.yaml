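# Adapter schema for external HDF5 motion-capture exports.
#
# This file documents how to map an external recording onto the stream
# layout read by chaintrack.io.read_stream; it is a mapping description for
# writing converters, not a parser configuration.
#
# chaintrack HDF5 stream layout (SI units):
#   /time            (T,)    seconds, strictly increasing, <=1% rate jitter
#   /<imu_id>/acc    (T, 3)  specific force, m/s^2, IMU frame
#   /<imu_id>/gyro   (T, 3)  angular rate, rad/s, IMU frame
#   /<imu_id>/mag    (T, 3)  magnetic field, arbitrary units (optional,
#                            required in the first sample for initialization)
#
# Typical external layout (one group per sensor, one dataset per channel):
expected_external_layout:
  per_imu_group: "sensors/<name>"
  datasets:
    accelerometer: {path: "acc", units: "m/s^2"}
    gyroscope: {path: "gyr", units: "rad/s"}
    magnetometer: {path: "mag", units: "a.u. or uT"}
  time: {path: "timestamps", units: "s or ms"}
conversion_notes:
  - Convert time stamps to seconds and resample to a constant rate if the
    source jitter exceeds 1%.
  - Convert gyro data given in deg/s to rad/s.
  - Magnetometer scaling is irrelevant (only the field direction is used);
    units need not be converted.
  - Map each source sensor name to a chaintrack imu_id and list that order
    in the topology document.
  - Subtract gyro biases over a marked static interval before tracking
    (chaintrack.estimator.subtract_static_bias).
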