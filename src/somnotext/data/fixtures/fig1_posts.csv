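post_id,subject_id,timestamp,text
p01,student,2015-10-05T09:30,first lecture of the week done already
p02,student,2015-10-05T22:00,library is packed tonight still going
p03,student,2015-10-05T23:00,sixteen hours awake and this essay is not writing itself
p04,student,2015-10-05T23:45,ok one more page then sleep i promise
p05,student,2015-10-06T10:00,four hours of sleep was a mistake
p06,student,2015-10-06T13:45,zzz
p07,student,2015-10-06T16:00,that nap changed nothing still so tired
p08,student,2015-10-06T22:30,why did i agree to a group project
p09,student,2015-10-07T08:15,new day new me eight is a lot of am
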