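# Default six-domain rule base.
#
# Thresholds are implementation-chosen defaults anchored on common clinical
# guidance (BP control target <130/80 mmHg; WHO impaired-fasting-glucose
# cutpoint 110 mg/dL; desirable total cholesterol <200 mg/dL; triglycerides
# <150 mg/dL; BMI overweight >=25, underweight <18.5; recommended sleep 7-9 h).
# They are meant to be re-parameterized for local calibration: edit this file,
# never the code.

fallbacks:
  physical_activity: maintain
  stress: maintain
  nutrition: maintain
  sleep: general
  adherence: general
  general_behaviors: reduce

rules:
  # -- physical activity: weekly exercise frequency bands
  - id: pa-initiate
    domain: physical_activity
    when: [[activity_days_week, <, 1]]
    then: initiate
    note: sedentary (no weekly activity) -> start a program
  - id: pa-increase
    domain: physical_activity
    when: [[activity_days_week, ">=", 1], [activity_days_week, <, 3]]
    then: increase
    note: 1-2 days/week is below the guideline frequency
  - id: pa-maintain
    domain: physical_activity
    when: [[activity_days_week, ">=", 3]]
    then: maintain
    note: ">=3 days/week meets the frequency target"

  # -- stress management: self-reported stress x blood-pressure severity
  - id: st-urgent-sbp
    domain: stress
    when: [[stress_level, ==, high], [systolic_bp, ">=", 160]]
    then: urgent
    weight: 2
    note: high stress with severely elevated systolic pressure
  - id: st-urgent-dbp
    domain: stress
    when: [[stress_level, ==, high], [diastolic_bp, ">=", 100]]
    then: urgent
    weight: 2
    note: high stress with severely elevated diastolic pressure
  - id: st-reduce
    domain: stress
    when: [[stress_level, ==, high]]
    then: reduce
    note: high self-reported stress -> reduce stressors

  # -- nutrition: metabolic indicators, lipid profile, body mass index
  - id: nu-glucose
    domain: nutrition
    when: [[glucose, ">=", 110]]
    then: reduce
    note: impaired fasting glucose (WHO cutpoint 110 mg/dL)
  - id: nu-cholesterol
    domain: nutrition
    when: [[cholesterol_total, ">=", 200]]
    then: reduce
    note: total cholesterol at or above the desirable limit
  - id: nu-triglycerides
    domain: nutrition
    when: [[triglycerides, ">=", 150]]
    then: reduce
    note: elevated triglycerides
  - id: nu-bmi-high
    domain: nutrition
    when: [[bmi, ">=", 25]]
    then: reduce
    note: overweight or obese
  - id: nu-underweight
    domain: nutrition
    when: [[bmi, <, 18.5]]
    then: increase
    note: underweight -> increase intake

  # -- sleep: nightly rest duration outside 7-9 h with uncontrolled BP
  - id: sl-short-sbp
    domain: sleep
    when: [[sleep_hours, <, 7], [systolic_bp, ">=", 130]]
    then: urgent
  - id: sl-short-dbp
    domain: sleep
    when: [[sleep_hours, <, 7], [diastolic_bp, ">=", 80]]
    then: urgent
  - id: sl-long-sbp
    domain: sleep
    when: [[sleep_hours, ">", 9], [systolic_bp, ">=", 130]]
    then: urgent
  - id: sl-long-dbp
    domain: sleep
    when: [[sleep_hours, ">", 9], [diastolic_bp, ">=", 80]]
    then: urgent

  # -- therapeutic adherence: compliance indicators x BP control status
  - id: ad-urgent-sbp
    domain: adherence
    when: [[on_medication, ==, "yes"], [medication_adherent, ==, "no"], [systolic_bp, ">=", 130]]
    then: urgent
    note: treated but non-adherent with uncontrolled systolic pressure
  - id: ad-urgent-dbp
    domain: adherence
    when: [[on_medication, ==, "yes"], [medication_adherent, ==, "no"], [diastolic_bp, ">=", 80]]
    then: urgent
  - id: ad-maintain
    domain: adherence
    when: [[medication_adherent, ==, "yes"], [systolic_bp, <, 130], [diastolic_bp, <, 80]]
    then: maintain
    note: adherent and at the BP control target

  # -- general health behaviors: smoking, alcohol, screen time
  - id: gb-smoking
    domain: general_behaviors
    when: [[smoker_status, ==, current]]
    then: urgent
  - id: gb-alcohol-frequent
    domain: general_behaviors
    when: [[alcohol_consumption, ==, frequent]]
    then: urgent
  - id: gb-screen
    domain: general_behaviors
    when: [[screen_time_hours, ">=", 6]]
    then: reduce
  - id: gb-alcohol-occasional
    domain: general_behaviors
    when: [[alcohol_consumption, ==, occasional]]
    then: reduce
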